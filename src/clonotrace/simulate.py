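"""Generative model of the high-MOI barcoded transduction–transformation assay.

The chain of simulators mirrors the experiment end to end:

1. ``simulate_library`` designs a pooled barcoded lentiviral library
   (distance-separated 10-nt barcodes, class-imbalanced titers).
2. ``simulate_transduction`` delivers Poisson-distributed proviral copies per
   cell at a chosen MOI, with construct identities drawn from the pool titers.
3. ``simulate_tumor`` selects transduced founders and grows a clonal tumour
   with labelled histologic regions.
4. ``simulate_single_cell_reads`` emits the single-cell amplicon FASTQ
   (substitution errors, ambient barcodes, allelic dropout, doublets).
5. ``simulate_region_bulk`` emits per-region bulk barcode counts, as after
   laser-capture microdissection and bulk amplicon sequencing.

Every simulator records ground truth, so downstream decoding can be checked
exactly, and derives all randomness from one integer seed through
counter-based substreams.
"""

from __future__ import annotations

import gzip
import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .models import (
    BARCODE_LENGTH,
    CellGenotype,
    CloneSpec,
    ConstructDefinition,
    NoiseModel,
    PoolModel,
    TransductionParams,
    TumorModel,
    hamming,
)
from .panel import END_3PRIME, END_5PRIME, END_GFP, AmpliconPanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# library design
# ---------------------------------------------------------------------------

def generate_barcodes(
    n: int,
    seed: int = 0,
    min_distance: int = 3,
    length: int = BARCODE_LENGTH,
    max_tries_per_barcode: int = 20000,
) -> list[str]:
    """Random DNA barcodes with pairwise Hamming distance >= ``min_distance``.

    Distance >= 3 guarantees single-substitution correction is unambiguous:
    no observed 10-mer can sit at distance 1 from two whitelist entries.
    """
    rng = substream(seed, "barcodes")
    accepted: list[str] = []
    tries = 0
    budget = max_tries_per_barcode * max(n, 1)
    while len(accepted) < n:
        tries += 1
        if tries > budget:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"distance >= {min_distance}; the design is too dense"
            )
        cand = "".join(chr(b) for b in rng.choice(_BASES, size=length))
        if all(hamming(cand, prev) >= min_distance for prev in accepted):
            accepted.append(cand)
    return accepted


def simulate_library(
    n_orf: int,
    n_shrna: int,
    class_imbalance: float = 1.0,
    seed: int = 0,
    orf_genes: Sequence[str] | None = None,
    shrna_genes: Sequence[str] | None = None,
) -> PoolModel:
    """Design a pooled barcoded library of ORF and shRNA constructs.

    ``class_imbalance`` is the fold-overrepresentation of each shRNA vector
    relative to each ORF vector in the pooled titers (shRNA vectors package
    more efficiently owing to the shorter distance between LTRs); the pools
    observed in practice start near tenfold.
    """
    if n_orf < 0 or n_shrna < 0 or n_orf + n_shrna < 1:
        raise ValueError("need at least one construct")
    if class_imbalance < 1:
        raise ValueError("class_imbalance must be >= 1")
    if orf_genes is not None and len(orf_genes) != n_orf:
        raise ValueError("orf_genes length must equal n_orf")
    if shrna_genes is not None and len(shrna_genes) != n_shrna:
        raise ValueError("shrna_genes length must equal n_shrna")

    n = n_orf + n_shrna
    barcodes = generate_barcodes(n, seed=seed)
    constructs: list[ConstructDefinition] = []
    for i in range(n_orf):
        gene = orf_genes[i] if orf_genes is not None else f"OrfGene{i + 1}"
        cid = gene if orf_genes is not None else f"ORF{i + 1:02d}"
        constructs.append(ConstructDefinition(cid, gene, "ORF", barcodes[i], barcodes[i]))
    for j in range(n_shrna):
        bc = barcodes[n_orf + j]
        gene = shrna_genes[j] if shrna_genes is not None else f"ShGene{j + 1}"
        cid = gene if shrna_genes is not None else f"SH{j + 1:02d}"
        constructs.append(ConstructDefinition(cid, gene, "shRNA", bc, bc))

    raw = np.array([1.0] * n_orf + [class_imbalance] * n_shrna)
    return PoolModel(constructs, raw / raw.sum())


# ---------------------------------------------------------------------------
# transduction
# ---------------------------------------------------------------------------

def simulate_transduction(
    pool: PoolModel, params: TransductionParams
) -> tuple[list[CellGenotype], pd.DataFrame]:
    """Transduce ``n_cells`` cells at the given MOI.

    Copies per cell are Poisson(moi); each integration's construct identity is
    an independent draw proportional to pool titer weights.  Returns the cell
    genotypes and a truth table (cell_id, n_copies, constructs).
    """
    rng = substream(params.seed, "transduction")
    copies = rng.poisson(params.moi, size=params.n_cells)
    total = int(copies.sum())
    ids = np.asarray(pool.construct_ids, dtype=object)
    draws = rng.choice(len(ids), size=total, p=pool.titer_weights)
    offsets = np.concatenate([[0], np.cumsum(copies)])

    cells: list[CellGenotype] = []
    rows = []
    for i in range(params.n_cells):
        picked = tuple(sorted(ids[draws[offsets[i]:offsets[i + 1]]]))
        cell_id = f"cell{i:05d}"
        cells.append(CellGenotype(cell_id, picked))
        rows.append((cell_id, int(copies[i]), ";".join(picked)))
    truth = pd.DataFrame(rows, columns=["cell_id", "n_copies", "constructs"])
    return cells, truth


# ---------------------------------------------------------------------------
# tumour growth
# ---------------------------------------------------------------------------

def tumor_from_spec(
    clones: Iterable[tuple[str, Iterable[str], float, str]],
    regions: Iterable[tuple[str, str, dict[str, float]]],
) -> TumorModel:
    """Build a tumour directly from an explicit clone/region specification.

    ``clones`` holds (clone_id, barcode construct ids, fitness, histology);
    clone frequencies are fitness weights normalised to 1.
    """
    specs = [
        CloneSpec(cid, frozenset(bcs), float(fit), hist)
        for cid, bcs, fit, hist in clones
    ]
    fitness = np.array([c.fitness for c in specs], dtype=float)
    if np.any(fitness <= 0):
        raise ValueError("clone fitness must be positive")
    return TumorModel(specs, fitness / fitness.sum(), list(regions))


def simulate_tumor(
    cells: Sequence[CellGenotype],
    n_clones: int,
    fitness_law: str | tuple | Sequence[float] = "uniform",
    regions: str | list[tuple[str, str, dict[str, float]]] = "pure",
    seed: int = 0,
    histologies: Sequence[str] | None = None,
) -> TumorModel:
    """Select transduced founders and grow a clonal tumour.

    ``fitness_law`` is "uniform", ("exponential", scale), or an explicit
    per-clone weight vector; clone frequencies are fitness normalised to 1.
    ``regions`` is "pure" (one pure region per clone) or an explicit list of
    (region_id, histology, composition) tuples.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    transduced = [c for c in cells if c.integrations]
    if not transduced:
        raise ValueError("no transduced cells: cannot found a tumour")
    if len(transduced) < n_clones:
        raise ValueError(
            f"only {len(transduced)} transduced cells for {n_clones} clones"
        )
    rng = substream(seed, "tumor")
    order = rng.permutation(len(transduced))
    founders: list[CellGenotype] = []
    seen: set[frozenset[str]] = set()
    for idx in order:
        genotype = frozenset(transduced[idx].integrations)
        if genotype in seen:
            continue
        seen.add(genotype)
        founders.append(transduced[idx])
        if len(founders) == n_clones:
            break
    if len(founders) < n_clones:
        raise ValueError(
            f"only {len(founders)} distinct transduced genotypes for {n_clones} clones"
        )

    if isinstance(fitness_law, str):
        if fitness_law != "uniform":
            raise ValueError(f"unknown fitness law {fitness_law!r}")
        fitness = np.ones(n_clones)
    elif isinstance(fitness_law, tuple) and fitness_law and fitness_law[0] == "exponential":
        fitness = rng.exponential(scale=float(fitness_law[1]), size=n_clones)
    else:
        fitness = np.asarray(fitness_law, dtype=float)
        if fitness.shape != (n_clones,) or np.any(fitness <= 0):
            raise ValueError("explicit fitness must be n_clones positive weights")

    if histologies is None:
        histologies = [f"histology{i + 1}" for i in range(n_clones)]
    specs = [
        CloneSpec(f"clone{i + 1}", frozenset(f.integrations), float(fitness[i]), histologies[i % len(histologies)])
        for i, f in enumerate(founders)
    ]
    if regions == "pure":
        region_list = [
            (f"region{i + 1}", specs[i].histology, {specs[i].clone_id: 1.0})
            for i in range(n_clones)
        ]
    else:
        region_list = list(regions)
    return TumorModel(specs, fitness / fitness.sum(), region_list)


# ---------------------------------------------------------------------------
# read depth law
# ---------------------------------------------------------------------------

def _zero_truncated_depths(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Zero-truncated depth draws with mean parameter ``mean`` and negative
    binomial overdispersion ``dispersion`` (variance = m + a*m^2; a=0 is the
    Poisson limit).  Truncation makes absence-of-reads the exclusive business
    of the dropout process."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion == 0:
        dist = stats.poisson(mean)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        dist = stats.nbinom(r, p)
    p0 = dist.cdf(0)
    u = p0 + (1.0 - p0) * rng.random(size)
    return np.asarray(dist.ppf(u), dtype=np.int64)


class _FastqWriter:
    """Gzipped text writer with a zeroed header mtime, so identical read
    streams produce byte-identical files (the determinism contract)."""

    def __init__(self, path):
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, compresslevel=1, mtime=0)
        self._txt = io.TextIOWrapper(self._gz, encoding="ascii")

    def write(self, s: str) -> None:
        self._txt.write(s)

    def close(self) -> None:
        self._txt.close()
        self._raw.close()


def _mutate(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=n_errors, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = [b for b in b"ACGT" if b != current]
        arr[pos] = choices[rng.integers(3)]
    return arr.decode("ascii")


# ---------------------------------------------------------------------------
# single-cell amplicon reads
# ---------------------------------------------------------------------------

def simulate_single_cell_reads(
    tumor: TumorModel,
    pool: PoolModel,
    noise: NoiseModel,
    n_cells: int,
    panel: AmpliconPanel,
    seed: int = 0,
    fastq_path=None,
) -> tuple[pd.DataFrame, object]:
    """Emit single-cell amplicon reads for a dissociated tumour.

    Each captured "cell" draws a clone (or, with probability ``doublet_rate``,
    two merged clones), then every barcode amplicon end of every carried
    construct plus the GFP amplicon receives a zero-truncated negative
    binomial number of reads, thinned by allelic dropout.  Barcode reads are
    replaced by tumour-background (ambient) constructs at ``ambient_fraction``
    and sequenced with per-base substitution errors in either orientation.
    The cell identifier travels in the read name (``@cell:<id>:<serial>``).

    Returns ``(truth, reads)`` where truth lists each cell's clone(s) and
    construct set, and reads is the FASTQ path (if ``fastq_path`` given) or a
    list of (name, sequence) tuples.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = substream(seed, "sc_reads")
    n_clones = len(tumor.clones)
    freqs = tumor.clone_frequencies

    clone_idx = rng.choice(n_clones, size=n_cells, p=freqs)
    is_doublet = rng.random(n_cells) < noise.doublet_rate
    partner_idx = rng.choice(n_clones, size=n_cells, p=freqs)

    amp5 = _require_end(panel, END_5PRIME)
    amp3 = _require_end(panel, END_3PRIME)
    ampg = _require_end(panel, END_GFP)

    barcode_of = {c.construct_id: c.barcode5 for c in pool.constructs}
    templates: dict[tuple[str, str | None], str] = {(END_GFP, None): ampg.template()}
    for cid, bc in barcode_of.items():
        templates[(END_5PRIME, cid)] = amp5.template(bc)
        templates[(END_3PRIME, cid)] = amp3.template(bc)

    marg = tumor.marginal_construct_frequencies()
    ambient_ids = np.asarray(sorted(marg), dtype=object)
    ambient_p = np.array([marg[c] for c in ambient_ids])

    # enumerate amplicon instances per cell
    inst_cell: list[int] = []
    inst_construct: list[str | None] = []
    inst_end: list[str] = []
    truth_rows = []
    for i in range(n_cells):
        clones_here = {tumor.clones[clone_idx[i]]}
        if is_doublet[i]:
            clones_here.add(tumor.clones[partner_idx[i]])
        constructs = sorted(set().union(*(c.barcode_set for c in clones_here)))
        cell_id = f"cell{i:05d}"
        truth_rows.append(
            (
                cell_id,
                ";".join(sorted(c.clone_id for c in clones_here)),
                ";".join(constructs),
                bool(is_doublet[i] and len(clones_here) > 1),
            )
        )
        for cid in constructs:
            inst_cell.extend((i, i))
            inst_construct.extend((cid, cid))
            inst_end.extend((END_5PRIME, END_3PRIME))
        inst_cell.append(i)
        inst_construct.append(None)
        inst_end.append(END_GFP)
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "clone_id", "constructs", "is_doublet"]
    )

    n_inst = len(inst_cell)
    depths = _zero_truncated_depths(
        rng, noise.reads_per_cell_mean, noise.reads_per_cell_dispersion, n_inst
    )
    if noise.dropout_prob > 0:
        depths[rng.random(n_inst) < noise.dropout_prob] = 0

    # expand to per-read arrays
    read_inst = np.repeat(np.arange(n_inst), depths)
    n_reads = len(read_inst)
    inst_has_bc = np.array([e != END_GFP for e in inst_end])
    ambient_mask = (
        (rng.random(n_reads) < noise.ambient_fraction)
        & inst_has_bc[read_inst]
        if noise.ambient_fraction > 0 and len(ambient_ids)
        else np.zeros(n_reads, dtype=bool)
    )
    ambient_draw = (
        rng.choice(len(ambient_ids), size=int(ambient_mask.sum()), p=ambient_p)
        if ambient_mask.any()
        else np.zeros(0, dtype=int)
    )
    flip = rng.random(n_reads) < 0.5
    inst_len = np.array([len(templates[(e, c)]) for e, c in zip(inst_end, inst_construct)])
    n_err = (
        rng.binomial(inst_len[read_inst], noise.per_base_error)
        if noise.per_base_error > 0
        else np.zeros(n_reads, dtype=np.int64)
    )

    out = _FastqWriter(fastq_path) if fastq_path is not None else None
    records: list[tuple[str, str]] = []
    try:
        amb_pos = 0
        for r in range(n_reads):
            inst = read_inst[r]
            end = inst_end[inst]
            construct = inst_construct[inst]
            if ambient_mask[r]:
                construct = ambient_ids[ambient_draw[amb_pos]]
                amb_pos += 1
            seq = templates[(end, construct)]
            if n_err[r]:
                seq = _mutate(seq, int(n_err[r]), rng)
            if flip[r]:
                seq = reverse_complement(seq)
            name = f"cell:cell{inst_cell[inst]:05d}:{r}"
            if out is not None:
                out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                records.append((name, seq))
    finally:
        if out is not None:
            out.close()
    return truth, (fastq_path if fastq_path is not None else records)


def _require_end(panel: AmpliconPanel, end_label: str):
    try:
        return panel.by_end(end_label)
    except KeyError:
        raise ValueError(f"panel lacks a {end_label} amplicon") from None


# ---------------------------------------------------------------------------
# bulk region counts
# ---------------------------------------------------------------------------

def simulate_region_bulk(
    tumor: TumorModel,
    noise: NoiseModel,
    reads_per_region: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk barcode counts for each microdissected region.

    Counts per construct are multinomial with probability proportional to the
    summed fractions of the region's clones carrying that construct, mixed
    with ``ambient_fraction`` of tumour-wide background.  Returns a long-form
    count table (region_id, histology, construct_id, count) and the region
    composition truth table.
    """
    if not tumor.regions:
        raise ValueError("tumour has no regions")
    if reads_per_region <= 0:
        raise ValueError("reads_per_region must be positive")
    rng = substream(seed, "region_bulk")

    marg = tumor.marginal_construct_frequencies()
    construct_ids = sorted(marg)
    background = np.array([marg[c] for c in construct_ids])
    membership = {
        clone.clone_id: np.array([c in clone.barcode_set for c in construct_ids], dtype=float)
        for clone in tumor.clones
    }

    count_rows = []
    truth_rows = []
    for region_id, histology, comp in tumor.regions:
        p = np.zeros(len(construct_ids))
        for clone_id, frac in comp.items():
            p += frac * membership[clone_id]
        if p.sum() == 0:
            raise ValueError(f"region {region_id!r} contains no barcoded clones")
        p = p / p.sum()
        p = (1.0 - noise.ambient_fraction) * p + noise.ambient_fraction * background
        counts = rng.multinomial(reads_per_region, p)
        for cid, n in zip(construct_ids, counts):
            count_rows.append((region_id, histology, cid, int(n)))
        for clone_id, frac in sorted(comp.items()):
            truth_rows.append((region_id, histology, clone_id, float(frac)))

    counts_df = pd.DataFrame(
        count_rows, columns=["region_id", "histology", "construct_id", "count"]
    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["region_id", "histology", "clone_id", "fraction"]
    )
    return counts_df, truth_df
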