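"""Domain types for the barcoded-lentivirus transformation assay.

The assay transduces primary epithelial cells at high multiplicity of
infection (MOI) with a pooled library of GFP-marked lentiviral constructs,
each carrying matching ten-nucleotide barcodes near the 5' and 3' LTRs.
Transduced cells are grafted, tumours grow by clonal selection, and each
tumour cell inherits the barcode combination of its founder.  These classes
describe the library, the transduction, the tumour, and the noise processes
of the downstream single-cell amplicon readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BARCODE_LENGTH = 10
_ALPHABET = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; non-ACGT symbols simply
    mismatch whatever they face."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ConstructDefinition:
    """One barcoded lentiviral construct in the pool.

    The two barcodes are designed identical (the same ten-mer is inserted
    distal to the 5' LTR and proximal to the 3' LTR) so that either amplicon
    end identifies the construct and 5'/3' discordance flags recombination.
    """

    construct_id: str
    gene_symbol: str
    perturbation_class: str  # "ORF" or "shRNA"
    barcode5: str
    barcode3: str

    def __post_init__(self) -> None:
        if self.perturbation_class not in ("ORF", "shRNA"):
            raise ValueError(
                f"perturbation_class must be ORF or shRNA, got {self.perturbation_class!r}"
            )
        for bc in (self.barcode5, self.barcode3):
            if len(bc) != BARCODE_LENGTH:
                raise ValueError(f"barcode {bc!r} is not {BARCODE_LENGTH} nt")
            if not _ALPHABET.issuperset(bc):
                raise ValueError(f"barcode {bc!r} contains non-ACGT symbols")
        if self.barcode5 != self.barcode3:
            raise ValueError("designed constructs carry matching 5'/3' barcodes")


@dataclass
class PoolModel:
    """A produced lentiviral pool: whitelist plus relative titer weights."""

    constructs: list[ConstructDefinition]
    titer_weights: np.ndarray

    def __post_init__(self) -> None:
        self.titer_weights = np.asarray(self.titer_weights, dtype=float)
        if len(self.titer_weights) != len(self.constructs):
            raise ValueError("one titer weight per construct required")
        if np.any(self.titer_weights < 0):
            raise ValueError("titer weights must be non-negative")
        if abs(self.titer_weights.sum() - 1.0) > 1e-9:
            raise ValueError("titer weights must sum to 1")
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            raise ValueError("construct ids must be unique")
        bcs = [c.barcode5 for c in self.constructs]
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be unique across the whitelist")

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def barcode_map(self) -> dict[str, str]:
        """barcode -> construct_id (5' and 3' barcodes match by design)."""
        return {c.barcode5: c.construct_id for c in self.constructs}


@dataclass(frozen=True)
class TransductionParams:
    """Poisson transduction: copies per cell ~ Poisson(moi), identities drawn
    proportional to pool titer weights."""

    moi: float
    n_cells: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


@dataclass(frozen=True)
class CellGenotype:
    """A cell with its multiset of proviral integrations (construct ids;
    repeated integration of the same construct is possible)."""

    cell_id: str
    integrations: tuple[str, ...]


@dataclass(frozen=True)
class CloneSpec:
    """A founder clone: its barcode combination, relative fitness, and the
    histology its descendants exhibit."""

    clone_id: str
    barcode_set: frozenset[str]
    fitness: float = 1.0
    histology: str = "unspecified"


@dataclass
class TumorModel:
    """Clonal tumour with labelled histologic regions.

    clone_frequencies are the cell fractions of each clone in the dissociated
    tumour; each region is a mixture over clones (pure regions have a single
    nonzero component).
    """

    clones: list[CloneSpec]
    clone_frequencies: np.ndarray
    regions: list[tuple[str, str, dict[str, float]]]  # (region_id, histology, {clone_id: frac})

    def __post_init__(self) -> None:
        self.clone_frequencies = np.asarray(self.clone_frequencies, dtype=float)
        if len(self.clone_frequencies) != len(self.clones):
            raise ValueError("one frequency per clone required")
        if abs(self.clone_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("clone frequencies must sum to 1")
        known = {c.clone_id for c in self.clones}
        for region_id, _hist, comp in self.regions:
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"region {region_id!r} composition must sum to 1")
            if not set(comp) <= known:
                raise ValueError(f"region {region_id!r} references unknown clones")

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def clone_by_id(self, clone_id: str) -> CloneSpec:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    def marginal_construct_frequencies(self) -> dict[str, float]:
        """Tumour-wide frequency of each construct (ambient background law)."""
        marg: dict[str, float] = {}
        for clone, freq in zip(self.clones, self.clone_frequencies):
            for cid in clone.barcode_set:
                marg[cid] = marg.get(cid, 0.0) + float(freq)
        total = sum(marg.values())
        if total > 0:
            marg = {k: v / total for k, v in marg.items()}
        return marg


@dataclass(frozen=True)
class NoiseModel:
    """Noise processes of the single-cell amplicon readout.

    per_base_error        substitution probability per sequenced base
    ambient_fraction      fraction of barcode reads drawn from the pooled
                          tumour background instead of the cell's own genotype
    dropout_prob          probability an amplicon present in a cell yields no
                          reads (allelic dropout / failed amplification)
    doublet_rate          probability a "cell" is two merged genotypes
    reads_per_cell_mean   mean reads per amplicon per cell (depth law)
    reads_per_cell_dispersion
                          negative-binomial overdispersion alpha with
                          var = m + alpha * m^2; 0 gives the Poisson limit.
                          Depth is zero-truncated: absence of reads is
                          governed solely by dropout_prob.
    """

    per_base_error: float = 1e-3
    ambient_fraction: float = 0.02
    dropout_prob: float = 0.05
    doublet_rate: float = 0.05
    reads_per_cell_mean: float = 50.0
    reads_per_cell_dispersion: float = 0.3

    def __post_init__(self) -> None:
        for name in ("per_base_error", "ambient_fraction", "dropout_prob", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_cell_mean <= 0:
            raise ValueError("reads_per_cell_mean must be > 0")
        if self.reads_per_cell_dispersion < 0:
            raise ValueError("reads_per_cell_dispersion must be >= 0")

    @classmethod
    def noiseless(cls, reads_per_cell_mean: float = 10.0) -> "NoiseModel":
        """All noise off; fixed depth (dispersion 0 + truncation at >=1)."""
        return cls(
            per_base_error=0.0,
            ambient_fraction=0.0,
            dropout_prob=0.0,
            doublet_rate=0.0,
            reads_per_cell_mean=reads_per_cell_mean,
            reads_per_cell_dispersion=0.0,
        )
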