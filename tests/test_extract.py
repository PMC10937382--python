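"""Barcode extraction tests: flank anchoring, whitelist correction, count
matrix accumulation, and 5'/3' concordance."""

import numpy as np
import pandas as pd
import pytest

from clonotrace.extract import (
    STATUS_AMBIGUOUS,
    STATUS_CORRECTED,
    STATUS_EXACT,
    STATUS_GFP,
    STATUS_NOMATCH,
    BarcodeCall,
    CellCountMatrix,
    build_cell_count_matrix,
    calls_from_reads,
    concordance_report,
    correct_to_whitelist,
    extract_reads,
    locate_and_extract,
)
from clonotrace.models import NoiseModel, hamming
from clonotrace.simulate import (
    generate_barcodes,
    reverse_complement,
    simulate_single_cell_reads,
    tumor_from_spec,
)

from clonotrace._rng import substream


# ---------------------------------------------------------------------------
# locate_and_extract
# ---------------------------------------------------------------------------

def test_exact_offset_extraction(panel, small_pool):
    amp = panel.by_end("5prime")
    bc = small_pool.constructs[0].barcode5
    hit = locate_and_extract(amp.template(bc), panel)
    assert hit.candidate == bc and hit.end_label == "5prime"
    assert hit.orientation == "+" and hit.shift == 0


def test_reverse_orientation_extraction(panel, small_pool):
    amp = panel.by_end("3prime")
    bc = small_pool.constructs[1].barcode5
    hit = locate_and_extract(reverse_complement(amp.template(bc)), panel)
    assert hit.candidate == bc and hit.orientation == "-"


def test_gfp_reads_hit_without_barcode(panel):
    amp = panel.by_end("gfp")
    hit = locate_and_extract(amp.template(), panel)
    assert hit.candidate is None and hit.end_label == "gfp"


def test_random_sequence_is_nomatch(panel):
    rng = substream(0, "random_read")
    seq = "".join(rng.choice(list("ACGT"), size=60))
    assert locate_and_extract(seq, panel) is None


def test_shifted_reads_match_sliding_oracle(panel, small_pool):
    """Positional shifts within the window recover the same barcode as a
    brute-force scan over every offset."""
    amp = panel.by_end("5prime")
    bc = small_pool.constructs[2].barcode5
    for shift in range(0, 4):
        read = "G" * shift + amp.template(bc) + "A" * (3 - shift)
        # oracle: scan all upstream-flank offsets for a perfect flank pair
        oracle = None
        for pos in range(len(read) - len(amp.upstream) - 10):
            if (
                read[pos:pos + len(amp.upstream)] == amp.upstream
                and read[pos + len(amp.upstream) + 10:
                         pos + len(amp.upstream) + 10 + len(amp.downstream)] == amp.downstream
            ):
                oracle = read[pos + len(amp.upstream):pos + len(amp.upstream) + 10]
                break
        hit = locate_and_extract(read, panel, shift_window=3)
        assert oracle == bc
        assert hit is not None and hit.candidate == oracle and hit.shift == shift
    # beyond the window the read is rejected
    read = "G" * 5 + amp.template(bc)
    assert locate_and_extract(read, panel, shift_window=3) is None


def test_flank_mismatch_tolerance(panel, small_pool):
    amp = panel.by_end("5prime")
    bc = small_pool.constructs[0].barcode5
    up = list(amp.upstream)
    up[3] = "A" if up[3] != "A" else "C"
    up[11] = "A" if up[11] != "A" else "C"
    read = "".join(up) + bc + amp.downstream
    assert locate_and_extract(read, panel, max_flank_mismatch=2).candidate == bc
    assert locate_and_extract(read, panel, max_flank_mismatch=1) is None


# ---------------------------------------------------------------------------
# correct_to_whitelist
# ---------------------------------------------------------------------------

def _brute_force(candidate, bc_map, max_h=1):
    dists = {bc: hamming(candidate, bc) for bc in bc_map}
    dmin = min(dists.values())
    winners = [bc for bc, d in dists.items() if d == dmin]
    if dmin == 0:
        return bc_map[winners[0]], STATUS_EXACT
    if dmin > max_h:
        return None, STATUS_NOMATCH
    if len(winners) > 1:
        return None, STATUS_AMBIGUOUS
    return bc_map[winners[0]], STATUS_CORRECTED


def test_correction_matches_brute_force_on_random_candidates():
    barcodes = generate_barcodes(25, seed=13)
    bc_map = {bc: f"K{i}" for i, bc in enumerate(barcodes)}
    rng = substream(1, "candidates")
    statuses_seen = set()
    for _ in range(3000):
        r = rng.random()
        base = barcodes[rng.integers(len(barcodes))]
        if r < 0.4:
            cand = base
        else:
            n_mut = 1 if r < 0.75 else int(rng.integers(2, 6))
            arr = list(base)
            for pos in rng.choice(10, size=n_mut, replace=False):
                arr[pos] = "ACGT"[(("ACGT".index(arr[pos])) + 1 + rng.integers(3)) % 4]
            cand = "".join(arr)
        cid, status, d = correct_to_whitelist(cand, bc_map)
        exp_cid, exp_status = _brute_force(cand, bc_map)
        assert (cid, status) == (exp_cid, exp_status)
        if status in (STATUS_EXACT, STATUS_CORRECTED):
            assert d <= 1
        statuses_seen.add(status)
    assert {STATUS_EXACT, STATUS_CORRECTED, STATUS_NOMATCH} <= statuses_seen


def test_ambiguous_tie_between_two_entries():
    bc_map = {"AAAAAAAAAA": "X", "AAAAAAAACC": "Y"}
    cid, status, d = correct_to_whitelist("AAAAAAAAAC", bc_map)
    assert cid is None and status == STATUS_AMBIGUOUS and d == 1


def test_non_acgt_symbols_count_as_mismatches():
    bc_map = {"AAAAAAAAAA": "X"}
    assert correct_to_whitelist("AAAAAAAAAN", bc_map)[1] == STATUS_CORRECTED
    assert correct_to_whitelist("AAAAAAAANN", bc_map)[1] == STATUS_NOMATCH


def test_correction_idempotent_and_order_invariant():
    barcodes = generate_barcodes(12, seed=21)
    bc_map = {bc: f"K{i}" for i, bc in enumerate(barcodes)}
    reversed_map = dict(reversed(list(bc_map.items())))
    for bc in barcodes:
        mutated = ("C" if bc[0] != "C" else "G") + bc[1:]
        cid, status, _ = correct_to_whitelist(mutated, bc_map)
        assert status == STATUS_CORRECTED and cid == bc_map[bc]
        # idempotence: the whitelist barcode of the match corrects to itself
        assert correct_to_whitelist(bc, bc_map) == (bc_map[bc], STATUS_EXACT, 0)
        # insertion order of the whitelist is irrelevant
        assert correct_to_whitelist(mutated, reversed_map)[:2] == (cid, status)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def test_count_matrix_matches_exhaustive_recount():
    rng = substream(2, "calls")
    constructs = [f"K{i}" for i in range(5)]
    calls = []
    for i in range(2000):
        cell = f"cell{rng.integers(8):02d}"
        r = rng.random()
        if r < 0.55:
            cid = constructs[rng.integers(5)]
            end = "5prime" if rng.random() < 0.5 else "3prime"
            calls.append(BarcodeCall(f"r{i}", cell, cid, end, 0, STATUS_EXACT))
        elif r < 0.7:
            calls.append(BarcodeCall(f"r{i}", cell, None, None, None, STATUS_GFP))
        elif r < 0.85:
            calls.append(BarcodeCall(f"r{i}", cell, None, "5prime", 1, STATUS_AMBIGUOUS))
        else:
            calls.append(BarcodeCall(f"r{i}", cell, None, None, None, STATUS_NOMATCH))
    ccm = build_cell_count_matrix(calls, constructs)
    # oracle: exhaustive grouping
    for call in calls:
        if call.status == STATUS_EXACT:
            sub = ccm.counts5 if call.end_label == "5prime" else ccm.counts3
            assert sub.loc[call.cell_id, call.construct_id] >= 1
    expected = {}
    for call in calls:
        if call.status == STATUS_EXACT:
            key = (call.cell_id, call.construct_id, call.end_label)
            expected[key] = expected.get(key, 0) + 1
    for (cell, cid, end), n in expected.items():
        sub = ccm.counts5 if end == "5prime" else ccm.counts3
        assert sub.loc[cell, cid] == n
    sc = ccm.qc["status_counts"]
    assert sum(sc.values()) == len(calls)
    assert sc[STATUS_GFP] == sum(ccm.gfp)


def test_empty_call_stream_gives_empty_matrix():
    ccm = build_cell_count_matrix([], ["K0"])
    assert ccm.counts5.empty and ccm.qc["n_reads"] == 0


def test_every_read_gets_exactly_one_status(small_pool, panel):
    tumor = tumor_from_spec(
        [("cl1", small_pool.construct_ids[:3], 1.0, "h")],
        [("r1", "h", {"cl1": 1.0})],
    )
    noise = NoiseModel(per_base_error=0.02, reads_per_cell_mean=10.0)
    _, records = simulate_single_cell_reads(tumor, small_pool, noise, 40, panel, seed=8)
    ccm = extract_reads(records, panel, small_pool)
    assert sum(ccm.qc["status_counts"].values()) == len(records) == ccm.qc["n_reads"]


def test_streaming_extraction_agrees_with_call_stream(small_pool, panel):
    """The cached fast path and the explicit per-read call path accumulate
    identical matrices."""
    tumor = tumor_from_spec(
        [("cl1", small_pool.construct_ids[:2], 2.0, "h1"),
         ("cl2", small_pool.construct_ids[2:5], 1.0, "h2")],
        [("r1", "h1", {"cl1": 1.0})],
    )
    noise = NoiseModel(per_base_error=0.01, ambient_fraction=0.05,
                       dropout_prob=0.1, doublet_rate=0.1,
                       reads_per_cell_mean=8.0, reads_per_cell_dispersion=0.5)
    _, records = simulate_single_cell_reads(tumor, small_pool, noise, 60, panel, seed=9)
    fast = extract_reads(records, panel, small_pool)
    slow = build_cell_count_matrix(
        calls_from_reads(records, panel, small_pool), small_pool.construct_ids
    )
    pd.testing.assert_frame_equal(fast.counts5, slow.counts5)
    pd.testing.assert_frame_equal(fast.counts3, slow.counts3)
    assert fast.qc["status_counts"] == slow.qc["status_counts"]


def test_noiseless_matrix_matches_truth_indicator(small_pool, panel):
    tumor = tumor_from_spec(
        [("cl1", small_pool.construct_ids[:2], 1.0, "h1"),
         ("cl2", small_pool.construct_ids[3:6], 1.0, "h2")],
        [("r1", "h1", {"cl1": 1.0})],
    )
    truth, records = simulate_single_cell_reads(
        tumor, small_pool, NoiseModel.noiseless(6.0), 80, panel, seed=10
    )
    ccm = extract_reads(records, panel, small_pool)
    truth_sets = truth.set_index("cell_id")["constructs"].str.split(";").map(set)
    for cell in ccm.cell_ids:
        detected = set(np.array(ccm.counts5.columns)[ccm.counts5.loc[cell] > 0])
        assert detected == truth_sets[cell]
        detected3 = set(np.array(ccm.counts3.columns)[ccm.counts3.loc[cell] > 0])
        assert detected3 == truth_sets[cell]
        assert ccm.gfp[cell] > 0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_noiseless_concordance_is_one(small_pool, panel):
    tumor = tumor_from_spec(
        [("cl1", small_pool.construct_ids[:3], 1.0, "h")],
        [("r1", "h", {"cl1": 1.0})],
    )
    _, records = simulate_single_cell_reads(
        tumor, small_pool, NoiseModel.noiseless(5.0), 50, panel, seed=11
    )
    rep = concordance_report(extract_reads(records, panel, small_pool))
    observed = rep[rep["n_observed"] > 0]
    assert (observed["concordance"] == 1.0).all()
    assert not observed["flagged"].any()


def test_one_sided_dropout_halves_concordance():
    idx = pd.Index([f"c{i}" for i in range(2000)], name="cell_id")
    rng = substream(3, "dropout")
    keep3 = rng.random(2000) < 0.5
    c5 = pd.DataFrame({"K0": np.ones(2000, dtype=int)}, index=idx)
    c3 = pd.DataFrame({"K0": keep3.astype(int)}, index=idx)
    gfp = pd.Series(1, index=idx)
    rep = concordance_report(CellCountMatrix(c5, c3, gfp), floor=0.9)
    assert rep.loc["K0", "concordance"] == pytest.approx(0.5, abs=0.05)
    assert bool(rep.loc["K0", "flagged"])


def test_recombinant_reads_flag_both_constructs(small_pool, panel):
    """5'-of-X / 3'-of-Y recombinants leave each construct supported by one
    end only, so both fall below the concordance floor."""
    x, y = small_pool.constructs[0], small_pool.constructs[1]
    amp5, amp3 = panel.by_end("5prime"), panel.by_end("3prime")
    gfp = panel.by_end("gfp")
    records = []
    for i in range(30):
        records.append((f"cell:c{i:02d}:a", amp5.template(x.barcode5)))
        records.append((f"cell:c{i:02d}:b", amp3.template(y.barcode3)))
        records.append((f"cell:c{i:02d}:g", gfp.template()))
    rep = concordance_report(extract_reads(records, panel, small_pool))
    assert bool(rep.loc[x.construct_id, "flagged"])
    assert bool(rep.loc[y.construct_id, "flagged"])
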