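"""Decode amplicon reads into per-cell (or per-region) barcode counts.

Reads are matched by their constant flank sequences (flank-anchored
extraction rather than general alignment: the amplicons are short, fixed
templates), the 10-mer between the flanks is corrected against the construct
whitelist with a Hamming budget of 1 (the whitelist is designed at pairwise
distance >= 3, so distance-1 correction is collision-free), and accepted
calls are accumulated into a cells x constructs count matrix with separate
5' and 3' sub-matrices and a GFP marker column.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import BARCODE_LENGTH, PoolModel, hamming
from .panel import END_3PRIME, END_5PRIME, END_GFP, Amplicon, AmpliconPanel
from .simulate import reverse_complement

STATUS_EXACT = "exact"
STATUS_CORRECTED = "corrected"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NOMATCH = "nomatch"
STATUS_GFP = "gfp"
STATUSES = (STATUS_EXACT, STATUS_CORRECTED, STATUS_AMBIGUOUS, STATUS_NOMATCH, STATUS_GFP)

GFP_COLUMN = "GFP"


@dataclass(frozen=True)
class ExtractionHit:
    """Flank-anchored hit in one read: the candidate 10-mer (None for the
    barcode-free GFP amplicon), which end it came from, and the orientation
    and positional shift at which the flanks matched."""

    candidate: str | None
    end_label: str
    amplicon: str
    orientation: str  # "+" forward, "-" reverse complement
    shift: int


@dataclass(frozen=True)
class BarcodeCall:
    read_id: str
    cell_id: str
    construct_id: str | None
    end_label: str | None
    hamming_distance: int | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        has_construct = self.construct_id is not None
        if has_construct != (self.status in (STATUS_EXACT, STATUS_CORRECTED)):
            raise ValueError("construct_id set iff status is exact/corrected")


def _mismatches_at(seq: str, pattern: str, pos: int, budget: int) -> int | None:
    """Mismatch count of ``pattern`` against ``seq`` at ``pos``; None if out
    of bounds or over ``budget``."""
    end = pos + len(pattern)
    if pos < 0 or end > len(seq):
        return None
    mm = 0
    for a, b in zip(seq[pos:end], pattern):
        if a != b:
            mm += 1
            if mm > budget:
                return None
    return mm


def locate_and_extract(
    read: str,
    panel: AmpliconPanel,
    max_flank_mismatch: int = 2,
    shift_window: int = 3,
) -> ExtractionHit | None:
    """Locate an amplicon in a read and pull out the candidate barcode.

    Both orientations are searched; positional shifts up to ``shift_window``
    either side of the expected barcode offset are tried nearest-first, and
    each flank tolerates up to ``max_flank_mismatch`` substitutions.
    Returns None when no amplicon matches (the read is counted as nomatch).
    """
    shifts = sorted(range(-shift_window, shift_window + 1), key=lambda s: (abs(s), s))
    for orientation, seq in (("+", read), ("-", reverse_complement(read))):
        for amp in panel:
            up_expected = amp.window[0] - len(amp.upstream)
            for shift in shifts:
                up_pos = up_expected + shift
                if _mismatches_at(seq, amp.upstream, up_pos, max_flank_mismatch) is None:
                    continue
                bc_pos = up_pos + len(amp.upstream)
                if amp.has_barcode:
                    down_pos = bc_pos + BARCODE_LENGTH
                    if _mismatches_at(seq, amp.downstream, down_pos, max_flank_mismatch) is None:
                        continue
                    candidate = seq[bc_pos:bc_pos + BARCODE_LENGTH]
                    return ExtractionHit(candidate, amp.end_label, amp.name, orientation, shift)
                return ExtractionHit(None, amp.end_label, amp.name, orientation, shift)
    return None


def correct_to_whitelist(
    candidate: str,
    whitelist: PoolModel | dict[str, str],
    max_hamming: int = 1,
) -> tuple[str | None, str, int | None]:
    """Match a candidate 10-mer to the whitelist with Hamming correction.

    Returns (construct_id, status, distance).  Exact hits are status
    ``exact``; a unique whitelist entry within ``max_hamming`` is
    ``corrected``; ties at the minimal distance are ``ambiguous``; anything
    farther is ``nomatch``.  Non-ACGT symbols simply mismatch every base.
    """
    if len(candidate) != BARCODE_LENGTH:
        raise ValueError(f"candidate must be {BARCODE_LENGTH} nt")
    bc_map = whitelist.barcode_map() if isinstance(whitelist, PoolModel) else whitelist
    construct = bc_map.get(candidate)
    if construct is not None:
        return construct, STATUS_EXACT, 0
    if max_hamming == 0:
        return None, STATUS_NOMATCH, None
    best_d = max_hamming + 1
    best: list[str] = []
    for bc, cid in bc_map.items():
        d = hamming(candidate, bc)
        if d < best_d:
            best_d, best = d, [cid]
        elif d == best_d:
            best.append(cid)
    if best_d > max_hamming:
        return None, STATUS_NOMATCH, None
    if len(best) > 1:
        return None, STATUS_AMBIGUOUS, best_d
    return best[0], STATUS_CORRECTED, best_d


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

class CellCountMatrix:
    """Cells x constructs read counts with 5'/3' sub-matrices and GFP column.

    ``counts`` sums the two barcode ends and appends the GFP column;
    ``counts5``/``counts3`` keep the per-end sub-matrices for concordance
    checks.  ``qc`` tallies read statuses and filtering events.
    """

    def __init__(
        self,
        counts5: pd.DataFrame,
        counts3: pd.DataFrame,
        gfp: pd.Series,
        qc: dict | None = None,
    ):
        if not counts5.columns.equals(counts3.columns) or not counts5.index.equals(counts3.index):
            raise ValueError("5' and 3' sub-matrices must share cells and constructs")
        if not gfp.index.equals(counts5.index):
            raise ValueError("GFP column must share the cell index")
        if (counts5.to_numpy() < 0).any() or (counts3.to_numpy() < 0).any() or (gfp < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts5 = counts5
        self.counts3 = counts3
        self.gfp = gfp
        self.qc = dict(qc or {})

    @property
    def construct_ids(self) -> list[str]:
        return list(self.counts5.columns)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts5.index)

    @property
    def counts(self) -> pd.DataFrame:
        merged = self.counts5 + self.counts3
        merged[GFP_COLUMN] = self.gfp
        return merged

    def subset_cells(self, cell_ids) -> "CellCountMatrix":
        return CellCountMatrix(
            self.counts5.loc[cell_ids],
            self.counts3.loc[cell_ids],
            self.gfp.loc[cell_ids],
            self.qc,
        )

    def to_tsv(self, path5, path3, path_merged=None) -> None:
        self.counts5.to_csv(path5, sep="\t", index_label="cell_id")
        self.counts3.to_csv(path3, sep="\t", index_label="cell_id")
        if path_merged is not None:
            self.counts.to_csv(path_merged, sep="\t", index_label="cell_id")

    @classmethod
    def from_tsv(cls, path5, path3, gfp_from=None) -> "CellCountMatrix":
        c5 = pd.read_csv(path5, sep="\t", index_col="cell_id")
        c3 = pd.read_csv(path3, sep="\t", index_col="cell_id")
        gfp5 = c5.pop(GFP_COLUMN) if GFP_COLUMN in c5.columns else pd.Series(0, index=c5.index)
        gfp3 = c3.pop(GFP_COLUMN) if GFP_COLUMN in c3.columns else pd.Series(0, index=c3.index)
        return cls(c5, c3, gfp5 + gfp3)


class _Tally:
    """Streaming accumulator shared by the call-stream and fast read paths."""

    def __init__(self, construct_ids: list[str]):
        self.construct_ids = list(construct_ids)
        self.col = {cid: j for j, cid in enumerate(self.construct_ids)}
        self.row: dict[str, int] = {}
        self.c5: list[dict[int, int]] = []
        self.c3: list[dict[int, int]] = []
        self.gfp: list[int] = []
        self.status_counts = dict.fromkeys(STATUSES, 0)

    def _row(self, cell_id: str) -> int:
        i = self.row.get(cell_id)
        if i is None:
            i = len(self.row)
            self.row[cell_id] = i
            self.c5.append({})
            self.c3.append({})
            self.gfp.append(0)
        return i

    def add(self, cell_id: str, status: str, construct_id: str | None, end_label: str | None) -> None:
        self.status_counts[status] += 1
        i = self._row(cell_id)
        if status == STATUS_GFP:
            self.gfp[i] += 1
        elif status in (STATUS_EXACT, STATUS_CORRECTED):
            j = self.col[construct_id]
            target = self.c5[i] if end_label == END_5PRIME else self.c3[i]
            target[j] = target.get(j, 0) + 1

    def matrix(self) -> CellCountMatrix:
        cells = sorted(self.row)
        order = [self.row[c] for c in cells]
        n, m = len(cells), len(self.construct_ids)
        a5 = np.zeros((n, m), dtype=np.int64)
        a3 = np.zeros((n, m), dtype=np.int64)
        gfp = np.zeros(n, dtype=np.int64)
        for out_i, src_i in enumerate(order):
            for j, v in self.c5[src_i].items():
                a5[out_i, j] = v
            for j, v in self.c3[src_i].items():
                a3[out_i, j] = v
            gfp[out_i] = self.gfp[src_i]
        idx = pd.Index(cells, name="cell_id")
        qc = {"status_counts": dict(self.status_counts), "n_reads": int(sum(self.status_counts.values()))}
        return CellCountMatrix(
            pd.DataFrame(a5, index=idx, columns=self.construct_ids),
            pd.DataFrame(a3, index=idx, columns=self.construct_ids),
            pd.Series(gfp, index=idx, name=GFP_COLUMN),
            qc,
        )


def build_cell_count_matrix(
    calls: Iterable[BarcodeCall], construct_ids: list[str]
) -> CellCountMatrix:
    """Accumulate a stream of barcode calls into a count matrix; ambiguous
    and nomatch calls are excluded from counts but tallied in ``qc``."""
    tally = _Tally(construct_ids)
    for call in calls:
        tally.add(call.cell_id, call.status, call.construct_id, call.end_label)
    return tally.matrix()


# ---------------------------------------------------------------------------
# read-stream extraction
# ---------------------------------------------------------------------------

def _cell_id_from_title(title: str) -> str:
    # simulator convention: "cell:<id>:<serial>" (or "region:<id>:<serial>")
    parts = title.split(":")
    if len(parts) >= 2 and parts[0] in ("cell", "region"):
        return parts[1]
    return title.split()[0]


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """(title, sequence) pairs from a (gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title, seq


class _ReadDecoder:
    """Per-sequence decoder with an exact fast path and a memo cache.

    Most reads are error-free copies of one of a few dozen templates, so the
    cache collapses the per-read cost to a dict lookup; novel sequences fall
    back to the tolerant flank search plus whitelist correction.
    """

    def __init__(self, panel: AmpliconPanel, whitelist: PoolModel | dict[str, str],
                 max_flank_mismatch: int, shift_window: int, max_hamming: int):
        self.panel = panel
        self.bc_map = whitelist.barcode_map() if isinstance(whitelist, PoolModel) else dict(whitelist)
        self.max_flank_mismatch = max_flank_mismatch
        self.shift_window = shift_window
        self.max_hamming = max_hamming
        self.bc_amps = [a for a in panel if a.has_barcode]
        self.gfp_amps = [a for a in panel if not a.has_barcode]
        self.cache: dict[str, tuple[str, str | None, str | None]] = {}

    def _fast(self, seq: str) -> tuple[str, str | None, str | None] | None:
        for oriented in (seq, reverse_complement(seq)):
            for amp in self.bc_amps:
                lo, hi = amp.window
                up_pos = lo - len(amp.upstream)
                if (
                    oriented[up_pos:lo] == amp.upstream
                    and oriented[hi:hi + len(amp.downstream)] == amp.downstream
                ):
                    cand = oriented[lo:hi]
                    cid = self.bc_map.get(cand)
                    if cid is not None:
                        return (STATUS_EXACT, cid, amp.end_label)
                    return self._correct(cand, amp.end_label)
            for amp in self.gfp_amps:
                up_pos = amp.window[0] - len(amp.upstream)
                if oriented[up_pos:amp.window[0]] == amp.upstream:
                    return (STATUS_GFP, None, amp.end_label)
        return None

    def _correct(self, candidate: str, end_label: str) -> tuple[str, str | None, str | None]:
        cid, status, _d = correct_to_whitelist(candidate, self.bc_map, self.max_hamming)
        return (status, cid, end_label if status in (STATUS_EXACT, STATUS_CORRECTED) else end_label)

    def _slow(self, seq: str) -> tuple[str, str | None, str | None]:
        hit = locate_and_extract(seq, self.panel, self.max_flank_mismatch, self.shift_window)
        if hit is None:
            return (STATUS_NOMATCH, None, None)
        if hit.candidate is None:
            return (STATUS_GFP, None, hit.end_label)
        return self._correct(hit.candidate, hit.end_label)

    def decode(self, seq: str) -> tuple[str, str | None, str | None]:
        res = self.cache.get(seq)
        if res is None:
            res = self._fast(seq) or self._slow(seq)
            self.cache[seq] = res
        return res


def extract_reads(
    reads,
    panel: AmpliconPanel,
    whitelist: PoolModel | dict[str, str],
    max_flank_mismatch: int = 2,
    shift_window: int = 3,
    max_hamming: int = 1,
) -> CellCountMatrix:
    """Decode a read stream into a cell (or region) count matrix.

    ``reads`` may be a FASTQ path, a list of FASTQ paths, or an iterable of
    (title, sequence) pairs.  The cell/region identifier is taken from the
    read title (``cell:<id>:...`` convention).
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        streams: Iterable[tuple[str, str]] = iter_fastq(reads)
    elif isinstance(reads, (list, tuple)) and reads and (
        isinstance(reads[0], (str, bytes)) and str(reads[0]).endswith((".fastq", ".fastq.gz", ".fq", ".fq.gz"))
        or hasattr(reads[0], "__fspath__")
    ):
        def _chain(paths):
            for p in paths:
                yield from iter_fastq(p)
        streams = _chain(reads)
    else:
        streams = iter(reads)

    if isinstance(whitelist, PoolModel):
        construct_ids = whitelist.construct_ids
    else:
        construct_ids = sorted(set(whitelist.values()))
    decoder = _ReadDecoder(panel, whitelist, max_flank_mismatch, shift_window, max_hamming)
    tally = _Tally(construct_ids)
    for title, seq in streams:
        status, cid, end_label = decoder.decode(seq)
        tally.add(_cell_id_from_title(title), status, cid, end_label)
    return tally.matrix()


def calls_from_reads(
    reads: Iterable[tuple[str, str]],
    panel: AmpliconPanel,
    whitelist: PoolModel | dict[str, str],
    max_flank_mismatch: int = 2,
    shift_window: int = 3,
    max_hamming: int = 1,
) -> Iterator[BarcodeCall]:
    """Explicit per-read calls (slower than ``extract_reads``; used for
    inspection and for checking the streaming path against the call stream)."""
    bc_map = whitelist.barcode_map() if isinstance(whitelist, PoolModel) else whitelist
    for title, seq in reads:
        cell_id = _cell_id_from_title(title)
        hit = locate_and_extract(seq, panel, max_flank_mismatch, shift_window)
        if hit is None:
            yield BarcodeCall(title, cell_id, None, None, None, STATUS_NOMATCH)
        elif hit.candidate is None:
            yield BarcodeCall(title, cell_id, None, hit.end_label, None, STATUS_GFP)
        else:
            cid, status, d = correct_to_whitelist(hit.candidate, bc_map, max_hamming)
            yield BarcodeCall(title, cell_id, cid, hit.end_label, d, status)


# ---------------------------------------------------------------------------
# 5'/3' concordance
# ---------------------------------------------------------------------------

def concordance_report(ccm: CellCountMatrix, floor: float = 0.9) -> pd.DataFrame:
    """Per-construct 5'/3' detection concordance.

    A (cell, construct) observation is concordant when both barcode ends are
    detected.  Constructs whose concordance falls below ``floor`` are flagged
    as suspected recombinants (a recombined provirus pairs the 5' barcode of
    one construct with the 3' barcode of another, so its reads support one
    end only).
    """
    det5 = ccm.counts5.to_numpy() > 0
    det3 = ccm.counts3.to_numpy() > 0
    either = det5 | det3
    both = det5 & det3
    n_obs = either.sum(axis=0)
    n_conc = both.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_obs > 0, n_conc / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame(
        {
            "n_observed": n_obs,
            "n_concordant": n_conc,
            "concordance": frac,
            "flagged": (n_obs > 0) & (frac < floor),
        },
        index=pd.Index(ccm.construct_ids, name="construct_id"),
    )
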