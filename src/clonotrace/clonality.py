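"""Single-cell clone calling: GFP filtering, barcode presence, clone
enumeration.

A clone is the set of cells sharing one distinct combination of lentiviral
barcodes.  Cells lacking any GFP amplicon reads are removed (untransduced or
failed captures), counts in each retained cell are normalised to that cell's
total construct counts, a barcode is called present at >= 1% of the cell's
counts, and clones are enumerated as the distinct presence sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extract import GFP_COLUMN, CellCountMatrix

DEFAULT_PRESENCE_THRESHOLD = 0.01
DEFAULT_MIN_CLONE_FRACTION = 0.05
RESIDUAL_LABEL = "residual"


def filter_gfp_cells(ccm: CellCountMatrix) -> CellCountMatrix:
    """Retain exactly the cells with at least one GFP amplicon read.

    GFP marks lentiviral transduction; barcode content of GFP-negative
    "cells" is ambient noise.  The number of removed cells is recorded in
    ``qc['cells_removed_no_gfp']``.
    """
    keep = ccm.gfp[ccm.gfp >= 1].index
    out = ccm.subset_cells(keep)
    out.qc = dict(ccm.qc)
    out.qc["cells_removed_no_gfp"] = int(len(ccm.cell_ids) - len(keep))
    out.qc["cells_retained"] = int(len(keep))
    return out


def call_presence(
    ccm_or_counts, threshold: float = DEFAULT_PRESENCE_THRESHOLD, ends: str = "union"
) -> pd.DataFrame:
    """Boolean presence matrix from per-cell normalised counts.

    For each cell, a construct's normalised value is its count divided by the
    cell's total construct counts (GFP excluded: it is a retention marker,
    not a clonal marker); the construct is present when that value reaches
    ``threshold`` (inclusive — the threshold names the smallest admitted
    value).  Cells with zero construct counts yield empty presence sets.
    ``ends`` selects "union" (5' + 3' counts, default) or "concordant"
    (minimum of the two ends, so both must support the barcode).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(ccm_or_counts, CellCountMatrix):
        if ends == "union":
            counts = ccm_or_counts.counts5 + ccm_or_counts.counts3
        elif ends == "concordant":
            counts = np.minimum(ccm_or_counts.counts5, ccm_or_counts.counts3)
        else:
            raise ValueError(f"unknown ends mode {ends!r}")
    else:
        counts = ccm_or_counts.drop(columns=[GFP_COLUMN], errors="ignore")
    values = counts.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, values / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(norm >= threshold, index=counts.index, columns=counts.columns)


@dataclass(frozen=True)
class Clone:
    clone_id: str
    barcode_set: frozenset[str]
    n_cells: int
    frequency: float
    dominant: bool = False
    doublet_flag: bool = False

    def barcode_key(self) -> str:
        return ";".join(sorted(self.barcode_set))


@dataclass
class ClonalArchitecture:
    """Clones ordered by descending cell count, plus the residual class
    (retained cells with empty presence sets) and the parameters used."""

    clones: list[Clone]
    residual_cells: int
    total_cells: int
    cell_assignments: pd.Series  # cell_id -> clone_id (or RESIDUAL_LABEL)
    parameters: dict = field(default_factory=dict)

    @property
    def residual_fraction(self) -> float:
        return self.residual_cells / self.total_cells if self.total_cells else 0.0

    def dominant_clones(self) -> list[Clone]:
        return [c for c in self.clones if c.dominant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [c.clone_id for c in self.clones],
                "barcode_set": [c.barcode_key() for c in self.clones],
                "n_cells": [c.n_cells for c in self.clones],
                "frequency": [c.frequency for c in self.clones],
                "dominant": [c.dominant for c in self.clones],
                "doublet_flag": [c.doublet_flag for c in self.clones],
            }
        )


def enumerate_clones(presence: pd.DataFrame) -> ClonalArchitecture:
    """Group cells by exact equality of their barcode presence sets.

    One clone per distinct non-empty set; frequencies are over all retained
    cells, so clone frequencies plus the residual fraction sum to 1.  Clones
    are ordered by descending cell count, ties broken lexicographically by
    the sorted barcode set.
    """
    cols = np.asarray(presence.columns, dtype=object)
    groups: dict[frozenset[str], list[str]] = {}
    mat = presence.to_numpy(dtype=bool)
    for cell, row in zip(presence.index, mat):
        key = frozenset(cols[row])
        groups.setdefault(key, []).append(cell)

    residual = groups.pop(frozenset(), [])
    total = len(presence.index)
    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), tuple(sorted(kv[0])))
    )
    clones = [
        Clone(
            clone_id=f"C{i + 1}",
            barcode_set=barcode_set,
            n_cells=len(cells),
            frequency=len(cells) / total if total else 0.0,
        )
        for i, (barcode_set, cells) in enumerate(ordered)
    ]
    assign = {}
    for clone, (_bs, cells) in zip(clones, ordered):
        for cell in cells:
            assign[cell] = clone.clone_id
    for cell in residual:
        assign[cell] = RESIDUAL_LABEL
    assignments = pd.Series(assign, name="clone_id").reindex(presence.index)
    assignments.index.name = "cell_id"
    return ClonalArchitecture(
        clones=clones,
        residual_cells=len(residual),
        total_cells=total,
        cell_assignments=assignments,
        parameters={},
    )


def select_dominant_clones(
    arch: ClonalArchitecture, min_cell_fraction: float = DEFAULT_MIN_CLONE_FRACTION
) -> ClonalArchitecture:
    """Annotate dominant clones and possible doublet artefacts.

    A clone is dominant when its cell fraction reaches ``min_cell_fraction``.
    A clone whose barcode set equals the union of two distinct dominant
    clones' sets (strictly containing each) is flagged as a possible doublet:
    two cells captured together read out as the merged combination.
    """
    if not 0 < min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must be in (0, 1)")
    dominant_sets = [c.barcode_set for c in arch.clones if c.frequency >= min_cell_fraction]
    union_sets: set[frozenset[str]] = set()
    for i in range(len(dominant_sets)):
        for j in range(i + 1, len(dominant_sets)):
            u = dominant_sets[i] | dominant_sets[j]
            if u > dominant_sets[i] and u > dominant_sets[j]:
                union_sets.add(u)
    clones = [
        Clone(
            clone_id=c.clone_id,
            barcode_set=c.barcode_set,
            n_cells=c.n_cells,
            frequency=c.frequency,
            dominant=c.frequency >= min_cell_fraction,
            doublet_flag=c.barcode_set in union_sets,
        )
        for c in arch.clones
    ]
    params = dict(arch.parameters)
    params["min_clone_fraction"] = min_cell_fraction
    return ClonalArchitecture(
        clones=clones,
        residual_cells=arch.residual_cells,
        total_cells=arch.total_cells,
        cell_assignments=arch.cell_assignments,
        parameters=params,
    )


def clonal_architecture(
    ccm: CellCountMatrix,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    min_cell_fraction: float = DEFAULT_MIN_CLONE_FRACTION,
    ends: str = "union",
) -> ClonalArchitecture:
    """GFP filter -> presence calls -> clone enumeration -> dominance."""
    filtered = filter_gfp_cells(ccm)
    presence = call_presence(filtered, threshold=threshold, ends=ends)
    arch = enumerate_clones(presence)
    arch = select_dominant_clones(arch, min_cell_fraction=min_cell_fraction)
    arch.parameters.update(
        {
            "presence_threshold": threshold,
            "ends": ends,
            "cells_removed_no_gfp": filtered.qc.get("cells_removed_no_gfp", 0),
        }
    )
    return arch
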