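"""Match laser-capture-microdissected region barcode profiles to single-cell
clones and partition constructs into shared vs clone-specific
genotype–histology associations.

Regions keep spatial/histologic context that single-cell dissociation loses;
clones keep exact barcode combinations that bulk sequencing cannot phase.
Matching region barcode sets to clone barcode sets joins the two."""

from __future__ import annotations

import pandas as pd

from .clonality import ClonalArchitecture

DEFAULT_REGION_THRESHOLD = 0.01
DEFAULT_AMBIGUITY_MARGIN = 0.1

CATEGORY_COMMON = "common-to-all-dominant-clones"
CATEGORY_SPECIFIC = "clone-specific"
CATEGORY_ABSENT = "absent"


def call_region_barcodes(
    region_counts: pd.DataFrame, rel_threshold: float = DEFAULT_REGION_THRESHOLD
) -> dict[str, set[str]]:
    """Presence sets per region from long-form bulk counts.

    ``region_counts`` has columns (region_id, histology, construct_id,
    count).  A construct is present in a region when its count reaches
    ``rel_threshold`` of the region total (inclusive; same boundary rule as
    the single-cell presence call)."""
    required = {"region_id", "construct_id", "count"}
    if not required <= set(region_counts.columns):
        raise ValueError(f"region counts need columns {sorted(required)}")
    sets: dict[str, set[str]] = {}
    for region_id, grp in region_counts.groupby("region_id", sort=True):
        total = grp["count"].sum()
        if total <= 0:
            raise ValueError(f"region {region_id!r} has zero total reads")
        frac = grp["count"] / total
        sets[region_id] = set(grp.loc[frac >= rel_threshold, "construct_id"])
    return sets


def region_histologies(region_counts: pd.DataFrame) -> dict[str, str]:
    if "histology" not in region_counts.columns:
        raise ValueError("region counts lack a histology column")
    return (
        region_counts.drop_duplicates("region_id")
        .set_index("region_id")["histology"]
        .to_dict()
    )


def _jaccard(a: set[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_regions_to_clones(
    region_sets: dict[str, set[str]],
    arch: ClonalArchitecture,
    min_margin: float = DEFAULT_AMBIGUITY_MARGIN,
    dominant_only: bool = True,
) -> pd.DataFrame:
    """Assign each region to the clone maximising the Jaccard index.

    Containment (fraction of the clone's set detected in the region) is
    reported alongside; an assignment is ambiguous when the Jaccard margin
    over the runner-up is below ``min_margin``.  Ties break deterministically
    by clone order (descending size), but are marked ambiguous."""
    clones = arch.dominant_clones() if dominant_only else arch.clones
    if not clones:
        raise ValueError("no clones to match against (no dominant clones?)")
    rows = []
    for region_id in sorted(region_sets):
        rset = region_sets[region_id]
        scores = [(_jaccard(rset, c.barcode_set), c) for c in clones]
        scores.sort(key=lambda sc: -sc[0])
        best_score, best = scores[0]
        runner_up = scores[1][0] if len(scores) > 1 else 0.0
        margin = best_score - runner_up
        containment = (
            len(rset & best.barcode_set) / len(best.barcode_set) if best.barcode_set else 0.0
        )
        rows.append(
            {
                "region_id": region_id,
                "clone_id": best.clone_id,
                "jaccard": best_score,
                "containment": containment,
                "margin": margin,
                "ambiguous": margin < min_margin,
            }
        )
    return pd.DataFrame(rows)


def genotype_histology_association(
    arch: ClonalArchitecture,
    assignments: pd.DataFrame,
    histology_by_region: dict[str, str],
    construct_ids: list[str],
) -> pd.DataFrame:
    """Partition the whitelist into shared, clone-specific, and absent events.

    Constructs carried by every dominant clone are common; constructs carried
    by exactly one dominant clone are clone-specific and annotated with the
    histologies of the regions matched (unambiguously) to that clone; all
    other constructs are absent from the dominant architecture."""
    if assignments.empty:
        raise ValueError("no region assignments provided")
    dominant = arch.dominant_clones()
    if not dominant:
        raise ValueError("architecture has no dominant clones")

    regions_of: dict[str, list[str]] = {}
    for row in assignments.itertuples(index=False):
        if not row.ambiguous:
            regions_of.setdefault(row.clone_id, []).append(row.region_id)

    rows = []
    for cid in construct_ids:
        carriers = [c for c in dominant if cid in c.barcode_set]
        if len(carriers) == len(dominant) and carriers:
            category, clone_id, hists = CATEGORY_COMMON, "", []
        elif len(carriers) == 1:
            clone = carriers[0]
            category, clone_id = CATEGORY_SPECIFIC, clone.clone_id
            hists = sorted(
                {histology_by_region[r] for r in regions_of.get(clone.clone_id, [])}
            )
        else:
            category, clone_id, hists = CATEGORY_ABSENT, "", []
        rows.append(
            {
                "construct_id": cid,
                "category": category,
                "clone_id": clone_id,
                "histologies": ";".join(hists),
            }
        )
    return pd.DataFrame(rows)


def deconvolve_regions(
    region_counts: pd.DataFrame,
    arch: ClonalArchitecture,
    construct_ids: list[str],
    rel_threshold: float = DEFAULT_REGION_THRESHOLD,
    min_margin: float = DEFAULT_AMBIGUITY_MARGIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full bulk deconvolution: presence calls, clone matching, association
    table.  Returns (region_assignments, genotype_histology)."""
    region_sets = call_region_barcodes(region_counts, rel_threshold)
    hists = region_histologies(region_counts)
    assignments = match_regions_to_clones(region_sets, arch, min_margin)
    assoc = genotype_histology_association(arch, assignments, hists, construct_ids)
    assignments = assignments.assign(
        histology=[hists[r] for r in assignments["region_id"]]
    )
    return assignments, assoc
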