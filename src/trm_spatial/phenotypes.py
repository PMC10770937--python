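"""Composite cell phenotypes derived from binary marker calls.

The taxonomy centres on CD8+ cytotoxic T cells and their tissue-resident
memory (T_RM) fraction, defined by CD103 co-expression:

* ``CD8``     — CD8+ T cell (CK−)
* ``CD103``   — any CD103+ cell (CK−), not necessarily CD8+
* ``TRM``     — CD103+CD8+ tissue-resident memory T cell
* ``TnonRM``  — CD8+CD103− T cell
* ``TRM1``–``TRM4`` — T_RM functional subsets by immune-checkpoint
  co-expression: PD-1−Tim-3− (TRM1), PD-1+Tim-3− (TRM2), PD-1−Tim-3+ (TRM3),
  PD-1+Tim-3+ (TRM4); they partition TRM.
* ``CK``      — cancer cell. Cells staining CK+ are classified as cancer even
  when co-staining CD8 (segmentation spill-over), keeping the cancer-cell set
  disjoint from every immune set.
* ``PD1CD8``/``TIM3CD8``/``GZMBCD8`` — checkpoint- or granzyme-positive CD8 cells.
* ``GZMB<label>`` — granzyme-B+ variant of each T-cell label (cytotoxicity
  readout; GZMB never enters a subset definition).

Panel 2 swaps the checkpoint/granzyme markers for CD31 (microvessel
endothelium) and Hif-1a (hypoxia): labels ``CD31`` and ``HIF1A``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import PANELS

TRM_SUBSETS = ("TRM1", "TRM2", "TRM3", "TRM4")

#: T-cell labels that get a GZMB+ variant
_TCELL_LABELS = ("CD8", "TRM", "TnonRM") + TRM_SUBSETS


def phenotype_masks(cells: pd.DataFrame, panel: str = "panel1") -> dict[str, np.ndarray]:
    """Vectorised phenotype calls: label -> boolean array over rows of *cells*."""
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}")
    ck = cells["CK"].to_numpy(dtype=bool)
    cd8 = cells["CD8"].to_numpy(dtype=bool) & ~ck
    cd103 = cells["CD103"].to_numpy(dtype=bool) & ~ck
    trm = cd8 & cd103
    tnon = cd8 & ~cd103
    masks: dict[str, np.ndarray] = {
        "CK": ck,
        "CD8": cd8,
        "CD103": cd103,
        "TRM": trm,
        "TnonRM": tnon,
    }
    if panel == "panel1":
        pd1 = cells["PD1"].to_numpy(dtype=bool)
        tim3 = cells["TIM3"].to_numpy(dtype=bool)
        gzmb = cells["GZMB"].to_numpy(dtype=bool)
        masks["TRM1"] = trm & ~pd1 & ~tim3
        masks["TRM2"] = trm & pd1 & ~tim3
        masks["TRM3"] = trm & ~pd1 & tim3
        masks["TRM4"] = trm & pd1 & tim3
        masks["PD1CD8"] = cd8 & pd1
        masks["TIM3CD8"] = cd8 & tim3
        for label in _TCELL_LABELS:
            masks[f"GZMB{label}"] = masks[label] & gzmb
    else:
        masks["CD31"] = cells["CD31"].to_numpy(dtype=bool)
        masks["HIF1A"] = cells["HIF1A"].to_numpy(dtype=bool)
    return masks


def classify_cell(markers: Mapping[str, bool], panel: str = "panel1") -> frozenset[str]:
    """All phenotype labels applying to one cell's marker calls.

    Pure function of the marker map; CK+ cells receive only the cancer label.
    """
    row = pd.DataFrame([{m: int(bool(v)) for m, v in markers.items()}])
    masks = phenotype_masks(row, panel=panel)
    return frozenset(label for label, mask in masks.items() if mask[0])


def gzmb_positive_fraction(cells: pd.DataFrame, subset: str) -> float:
    """Proportion of GZMB+ cells within a CD8-derived *subset* (cytotoxicity).

    Returns NaN (missing, not zero) when the subset is empty.
    """
    masks = phenotype_masks(cells, panel="panel1")
    if subset not in masks:
        raise KeyError(subset)
    sub = masks[subset]
    n = int(sub.sum())
    if n == 0:
        return float("nan")
    gzmb = cells["GZMB"].to_numpy(dtype=bool)
    return float((sub & gzmb).sum() / n)


def composition_fraction(cells: pd.DataFrame, numerator: str, denominator: str,
                         panel: str = "panel1") -> float:
    """Nested proportion count(numerator)/count(denominator); NaN when the
    denominator phenotype is absent."""
    masks = phenotype_masks(cells, panel=panel)
    den = int(masks[denominator].sum())
    if den == 0:
        return float("nan")
    return float(masks[numerator].sum() / den)


def subset_composition(cells: pd.DataFrame) -> dict[str, float]:
    """Fractions of the four T_RM subsets among T_RM cells (sum to 1)."""
    return {s: composition_fraction(cells, s, "TRM") for s in TRM_SUBSETS}
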