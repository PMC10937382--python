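"""Assay QC math: ddCT quantification, MOI estimation, and pooled-library
representation reporting and rebalancing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._rng import substream
from .models import PoolModel


# ---------------------------------------------------------------------------
# ddCT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdctInput:
    """Paired target/reference Ct values for a sample and a calibrator.

    dCT = Ct(target) - Ct(reference) within each of sample and calibrator;
    ddCT = dCT(sample) - dCT(calibrator).  In copy-number mode the calibrator
    has a known copy count (e.g. genomic DNA from a transgenic animal with
    one or two GFP copies)."""

    sample_target_ct: float
    sample_reference_ct: float
    calibrator_target_ct: float
    calibrator_reference_ct: float
    calibrator_copies: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "sample_target_ct",
            "sample_reference_ct",
            "calibrator_target_ct",
            "calibrator_reference_ct",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def ddct(self) -> float:
        d_sample = self.sample_target_ct - self.sample_reference_ct
        d_cal = self.calibrator_target_ct - self.calibrator_reference_ct
        return d_sample - d_cal


def ddct_copy_number(inp: DdctInput) -> float:
    """Sample copy number = calibrator copy number x 2^(-ddCT)."""
    if inp.calibrator_copies is None:
        raise ValueError("copy-number mode requires calibrator_copies")
    return inp.calibrator_copies * 2.0 ** (-inp.ddct)


def ddct_relative_expression(inp: DdctInput) -> float:
    """Fold change relative to the calibrator condition: 2^(-ddCT)."""
    return 2.0 ** (-inp.ddct)


# ---------------------------------------------------------------------------
# MOI estimation
# ---------------------------------------------------------------------------

def _zt_poisson_mle(mean_observed: float) -> float:
    """Rate of a zero-truncated Poisson with observed mean m: solve
    lam / (1 - exp(-lam)) = m.  m must exceed 1 (truncated support)."""
    if mean_observed <= 1:
        raise ValueError("zero-truncated mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean_observed
    lo = 1e-9
    hi = mean_observed  # lam <= m always; f(m) >= 0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def estimate_moi_from_fraction(positive_fraction: float) -> float:
    """MOI from the transduced (e.g. GFP+) cell fraction under the Poisson
    infection model: P(>=1 copy) = 1 - exp(-moi), so moi = -ln(1 - p)."""
    if not 0 <= positive_fraction < 1:
        raise ValueError("positive_fraction must be in [0, 1); 1 gives an unbounded MOI")
    return float(-np.log1p(-positive_fraction))


def estimate_moi(
    vcn_histogram=None,
    positive_fraction: float | None = None,
    zero_truncated: bool = False,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Estimate MOI (Poisson rate of copies per cell), with a bootstrap CI.

    Either ``positive_fraction`` (fraction of cells with >= 1 copy) or
    ``vcn_histogram`` (mapping copy-number -> cell count, or per-cell copy
    array) must be given.  With ``zero_truncated`` the zero class is treated
    as unobserved — the situation of a single-cell assay that only captures
    transduced cells — and the rate comes from the zero-truncated Poisson
    maximum likelihood.
    """
    if (vcn_histogram is None) == (positive_fraction is None):
        raise ValueError("provide exactly one of vcn_histogram or positive_fraction")
    if positive_fraction is not None:
        return {"moi": estimate_moi_from_fraction(positive_fraction), "ci": None}

    if isinstance(vcn_histogram, dict):
        ks = np.array(sorted(vcn_histogram), dtype=float)
        ns = np.array([vcn_histogram[int(k)] for k in ks], dtype=float)
    else:
        copies = np.asarray(vcn_histogram)
        ks, ns = np.unique(copies, return_counts=True)
        ks = ks.astype(float)
        ns = ns.astype(float)
    if ns.sum() == 0:
        raise ValueError("empty histogram")
    if zero_truncated:
        keep = ks > 0
        ks, ns = ks[keep], ns[keep]
        if ns.sum() == 0:
            raise ValueError("zero-truncated histogram has no positive classes")

    def _fit(counts: np.ndarray) -> float:
        m = float((ks * counts).sum() / counts.sum())
        if zero_truncated:
            if m <= 1:
                return 0.0  # degenerate: everything in the one-copy class
            return _zt_poisson_mle(m)
        return m

    estimate = _fit(ns)
    rng = substream(seed, "moi_bootstrap")
    n_total = int(ns.sum())
    p = ns / ns.sum()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _fit(rng.multinomial(n_total, p).astype(float))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return {"moi": estimate, "ci": (float(lo), float(hi)), "n_cells": n_total}


# ---------------------------------------------------------------------------
# library representation
# ---------------------------------------------------------------------------

@dataclass
class RepresentationReport:
    """Per-construct representation of a pooled library from bulk barcode
    sequencing, with class-level (ORF vs shRNA) summaries."""

    table: pd.DataFrame  # construct_id, perturbation_class, count, fraction, fold_vs_uniform, dropout
    class_means: dict[str, float]
    class_ratio: float  # mean shRNA fraction / mean ORF fraction
    cv: float  # coefficient of variation of fractions

    @property
    def fractions(self) -> pd.Series:
        return self.table.set_index("construct_id")["fraction"]


def representation_report(counts, pool: PoolModel) -> RepresentationReport:
    """Summarise pooled-library representation from construct read counts.

    ``counts`` maps construct_id -> reads (dict or Series); whitelist
    constructs without reads appear with fraction 0 and a dropout flag.
    fold-vs-uniform is fraction x number of constructs (1 = perfectly even).
    """
    counts = pd.Series(counts, dtype=float)
    ids = pool.construct_ids
    counts = counts.reindex(ids).fillna(0.0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total read count must be positive")
    frac = counts / total
    classes = pd.Series(
        {c.construct_id: c.perturbation_class for c in pool.constructs}
    ).reindex(ids)
    table = pd.DataFrame(
        {
            "construct_id": ids,
            "perturbation_class": classes.to_numpy(),
            "count": counts.to_numpy(),
            "fraction": frac.to_numpy(),
            "fold_vs_uniform": (frac * len(ids)).to_numpy(),
            "dropout": (counts == 0).to_numpy(),
        }
    )
    class_means = frac.groupby(classes).mean().to_dict()
    orf_mean = class_means.get("ORF", np.nan)
    sh_mean = class_means.get("shRNA", np.nan)
    ratio = float(sh_mean / orf_mean) if orf_mean and np.isfinite(orf_mean) else float("nan")
    cv = float(frac.std(ddof=0) / frac.mean()) if frac.mean() > 0 else float("nan")
    return RepresentationReport(table=table, class_means=class_means, class_ratio=ratio, cv=cv)


def rebalance_plan(report: RepresentationReport, floor: float = 1e-4) -> pd.Series:
    """Producer re-array plan: weight each construct inversely to its
    observed pool fraction.

    Formalises the empirical producer-surface-area adjustment: constructs
    overrepresented in the pool get proportionally less production capacity
    in the next arrayed round.  Zero-read constructs are floored at ``floor``
    to avoid unbounded weights.  Weights are normalised to sum to 1.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    frac = report.fractions
    w = 1.0 / np.maximum(frac.to_numpy(), floor)
    w = w / w.sum()
    return pd.Series(w, index=frac.index, name="production_weight")


def apply_rebalance(pool: PoolModel, plan: pd.Series) -> PoolModel:
    """New pool with titers proportional to old titer x production weight
    (one round of rebalanced arrayed production)."""
    w = plan.reindex(pool.construct_ids).to_numpy()
    new = pool.titer_weights * w
    return PoolModel(pool.constructs, new / new.sum())
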