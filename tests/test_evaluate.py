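"""Evaluation suite: gene conservation tests, deletion scans, alignment
and identity scoring, threshold accumulation, and k-mer counting."""

import numpy as np
import pandas as pd
import pytest

from xspecnorm.evaluate import (
    align_orthologs,
    classify_matches,
    conserved_gene_test,
    deletion_scan,
    kmer_frequency,
    probe_identity,
    ratio_track,
    threshold_accumulation,
)
from xspecnorm.thermo import reverse_complement

from conftest import random_dna


# ------------------------------------------------------------ conserved


def _probes_for_genes(gene_sizes):
    rows = []
    for g, size in gene_sizes.items():
        for j in range(size):
            rows.append(
                {"probe_id": f"{g}_p{j}", "gene_id": g, "region": "exon"}
            )
    return pd.DataFrame(rows)


def test_all_zero_ai_yields_no_calls():
    probes = _probes_for_genes({"g1": 4, "g2": 4})
    ai = pd.DataFrame({"probe_id": probes["probe_id"], "ai": 0.0})
    res = conserved_gene_test(ai, probes)
    assert not res["significant"].any()


def test_hand_t_statistic():
    # ai = (2.1, 1.9, 2.0, 2.2, 1.8): t = 2.0 / (0.1581.../sqrt 5) ≈ 28.28
    probes = _probes_for_genes({"g1": 5})
    ai = pd.DataFrame(
        {"probe_id": probes["probe_id"], "ai": [2.1, 1.9, 2.0, 2.2, 1.8]}
    )
    res = conserved_gene_test(ai, probes)
    vals = np.array([2.1, 1.9, 2.0, 2.2, 1.8])
    expected_t = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
    assert res.loc[0, "t_stat"] == pytest.approx(expected_t, abs=1e-9)
    assert res.loc[0, "t_stat"] == pytest.approx(28.2843, abs=1e-3)
    assert bool(res.loc[0, "significant"])


def test_small_genes_excluded_not_error():
    probes = _probes_for_genes({"g1": 1, "g2": 3})
    ai = pd.DataFrame({"probe_id": probes["probe_id"], "ai": 1.0})
    res = conserved_gene_test(ai, probes)
    assert list(res["gene_id"]) == ["g2"]


def test_planted_shift_recovered(rng):
    """100 genes, 10 carrying a +1.5 shift (σ=0.5, 8 probes/gene): all 10
    and only those called at family-wise 0.05."""
    genes = {f"g{i:03d}": 8 for i in range(100)}
    probes = _probes_for_genes(genes)
    shifted = {f"g{i:03d}" for i in range(10)}
    ai_vals = []
    for g, size in genes.items():
        mu = 1.5 if g in shifted else 0.0
        ai_vals.extend(rng.normal(mu, 0.5, size))
    res = conserved_gene_test(
        pd.DataFrame({"probe_id": probes["probe_id"], "ai": ai_vals}), probes
    )
    called = set(res.loc[res["significant"], "gene_id"])
    assert called == shifted


def test_bonferroni_threshold_consistency(rng):
    probes = _probes_for_genes({f"g{i}": 4 for i in range(20)})
    ai = pd.DataFrame(
        {"probe_id": probes["probe_id"], "ai": rng.normal(0, 1, len(probes))}
    )
    res = conserved_gene_test(ai, probes, alpha_fw=0.05)
    assert (res.loc[res["significant"], "p_raw"] <= 0.05 / len(res)).all()


# ------------------------------------------------------------ ratio/scan


def _track(ratios, spacing=35):
    n = len(ratios)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chromosome": "chrI",
            "position": np.arange(n) * spacing,
            "ratio": ratios,
        }
    )


def test_ratio_track_identities(small_probes):
    tgt = small_probes[small_probes["category"] == "target"]
    ai_ref = pd.DataFrame({"probe_id": tgt["probe_id"], "ai": [0.5, 1.0, -0.3]})
    ai_same = ai_ref.copy()
    track = ratio_track(ai_same, ai_ref, tgt)
    np.testing.assert_allclose(track["ratio"], 1.0)
    ai_up = ai_ref.copy()
    ai_up["ai"] = ai_up["ai"] + np.log(2)
    track2 = ratio_track(ai_up, ai_ref, tgt)
    np.testing.assert_allclose(track2["ratio"], 2.0)


def test_ratio_track_matches_naive_loop(rng, small_probes):
    tgt = small_probes[small_probes["category"] == "target"]
    n = 500
    ids = [f"p{i}" for i in range(n)]
    probes = pd.DataFrame(
        {"probe_id": ids, "chromosome": "chrI", "start": np.arange(n) * 35,
         "category": "target"}
    )
    a = pd.DataFrame({"probe_id": ids, "ai": rng.normal(size=n)})
    b = pd.DataFrame({"probe_id": ids, "ai": rng.normal(size=n)})
    track = ratio_track(a, b, probes).set_index("probe_id")
    av, bv = a.set_index("probe_id")["ai"], b.set_index("probe_id")["ai"]
    for p in ids[::37]:
        assert track.loc[p, "ratio"] == pytest.approx(np.exp(av[p] - bv[p]))


def test_ratio_track_excludes_one_sided_probes(small_probes):
    tgt = small_probes[small_probes["category"] == "target"]
    a = pd.DataFrame({"probe_id": ["t1", "t2"], "ai": [0.0, 0.0]})
    b = pd.DataFrame({"probe_id": ["t2", "t3"], "ai": [0.0, 0.0]})
    track = ratio_track(a, b, tgt)
    assert list(track["probe_id"]) == ["t2"]


def test_flat_track_calls_nothing():
    assert deletion_scan(_track(np.ones(200))).empty


def test_empty_track_ok():
    assert deletion_scan(_track(np.array([]))).empty


def test_planted_run_called_exactly():
    ratios = np.ones(200)
    ratios[80:120] = 0.3
    calls = deletion_scan(
        _track(ratios), window_probes=5, ratio_threshold=0.5, min_run=10
    )
    assert len(calls) == 1
    row = calls.iloc[0]
    # windowed median extends at most (window//2) probes past the run
    assert abs(row["start"] - 80 * 35) <= 2 * 35
    assert abs(row["end"] - (119 * 35 + 25)) <= 2 * 35
    assert row["mean_ratio"] < 0.5


def test_short_run_not_called():
    ratios = np.ones(200)
    ratios[80:85] = 0.3
    calls = deletion_scan(
        _track(ratios), window_probes=1, ratio_threshold=0.5, min_run=10
    )
    assert calls.empty


def test_scan_parameter_validation():
    with pytest.raises(ValueError):
        deletion_scan(_track(np.ones(5)), ratio_threshold=1.5)
    with pytest.raises(ValueError):
        deletion_scan(_track(np.ones(5)), window_probes=0)


# ------------------------------------------------------------ alignment


def naive_best_score(a, b, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    """Exhaustive enumeration of global alignments (tiny inputs only)."""

    best = -np.inf

    def gap_cost(length):
        return 0 if length == 0 else gap_open + (length - 1) * gap_extend

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "m")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "a" else gap_open), "a")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "b" else gap_open), "b")

    rec(0, 0, 0.0, "m")
    return best


def test_identical_sequences_align_gapless():
    ga, gb, score = align_orthologs("ACGTAC", "ACGTAC")
    assert ga == gb == "ACGTAC"
    assert score == 6


def test_single_gap_hand_score():
    ga, gb, score = align_orthologs("ACGT", "ACT")
    assert score == 3 * 1 + (-5)
    assert sum(c == "-" for c in gb) == 1


def test_score_symmetric_under_swap():
    a, b = "ACGTTGCA", "AGGTTGA"
    assert align_orthologs(a, b)[2] == align_orthologs(b, a)[2]


def test_matches_exhaustive_enumeration(rng):
    for _ in range(30):
        a = random_dna(rng, int(rng.integers(1, 7)))
        b = random_dna(rng, int(rng.integers(1, 7)))
        assert align_orthologs(a, b)[2] == pytest.approx(naive_best_score(a, b))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_orthologs("", "ACGT")


# ------------------------------------------------------------ identity


def naive_probe_matches(ref_g, alt_g, start, length):
    """Column-by-column counter over the probe's ungapped-reference span."""
    count, ref_pos = 0, 0
    for ra, aa in zip(ref_g, alt_g):
        if ra != "-":
            if start <= ref_pos < start + length and ra == aa and aa != "-":
                count += 1
            ref_pos += 1
    return count


def test_identical_ortholog_all_true():
    seq = "ACGT" * 20
    res = probe_identity((seq, seq), [0, 10, 55], probe_length=25)
    assert (res["matches"] == 25).all()
    assert (res["identity_class"] == "true").all()


def test_two_substitutions_semi_true():
    ref = "A" * 30
    alt = "A" * 5 + "C" + "A" * 10 + "G" + "A" * 13
    res = probe_identity((ref, alt), [0], probe_length=25)
    assert res.loc[0, "matches"] == 23
    assert res.loc[0, "identity_class"] == "semi-true"


def test_gap_columns_count_as_mismatch():
    ref = "ACGTACGTACGTACGTACGTACGTACGTAC"
    alt = ref[:10] + "---" + ref[13:]
    res = probe_identity((ref, alt), [0], probe_length=25)
    assert res.loc[0, "matches"] == 22


def test_matches_naive_counter_on_random_alignments(rng):
    from xspecnorm.synth import generate_ortholog_pair

    for k in range(25):
        _, _, (ga, gb) = generate_ortholog_pair(
            120, divergence_per_site=0.15, indel_rate=0.03, seed=1000 + k
        )
        ref_len = len(ga.replace("-", ""))
        starts = list(range(0, ref_len - 25, 11))
        res = probe_identity((ga, gb), starts, probe_length=25)
        for s, m in zip(starts, res["matches"]):
            assert m == naive_probe_matches(ga, gb, s, 25)


def test_probe_span_exceeding_reference_rejected():
    with pytest.raises(ValueError, match="span"):
        probe_identity(("ACGTACGT", "ACGTACGT"), [0], probe_length=25)


@pytest.mark.parametrize(
    "matches,expected",
    [(25, "true"), (24, "semi-true"), (23, "semi-true"), (22, "false"), (0, "false")],
)
def test_identity_class_boundaries(matches, expected):
    assert classify_matches(matches) == expected


def test_matches_cannot_exceed_length():
    with pytest.raises(ValueError):
        classify_matches(26)


# ------------------------------------------------------ accumulation


def _identities(pairs):
    return pd.DataFrame(
        {
            "probe_id": [p for p, _ in pairs],
            "matches": [m for _, m in pairs],
            "identity_class": [classify_matches(m) for _, m in pairs],
        }
    )


def test_hand_worked_accumulation():
    ids = _identities([("a", 25), ("b", 25), ("c", 24), ("d", 20), ("e", 19)])
    ratios = pd.Series({"a": 1.2, "b": 1.0, "c": 0.9, "d": 1.1, "e": 0.5})
    curve = threshold_accumulation(ratios, ids, [1.0])
    row = curve.iloc[0]
    assert (row["n_true"], row["n_semi_true"], row["n_false"]) == (2, 0, 1)
    assert row["mismatch_to_perfect"] == pytest.approx(0.5)


def test_counts_non_increasing_in_threshold(rng):
    n = 300
    ids = _identities([(f"p{i}", int(rng.integers(0, 26))) for i in range(n)])
    ratios = pd.Series(rng.lognormal(0, 0.5, n), index=[f"p{i}" for i in range(n)])
    curve = threshold_accumulation(ratios, ids, np.linspace(0.1, 3.0, 30))
    for col in ("n_true", "n_semi_true", "n_false"):
        assert (np.diff(curve[col]) <= 0).all()


def test_no_probe_above_top_threshold():
    ids = _identities([("a", 25), ("b", 10)])
    ratios = pd.Series({"a": 1.0, "b": 0.8})
    row = threshold_accumulation(ratios, ids, [5.0]).iloc[0]
    assert row["n_true"] == row["n_false"] == 0
    assert np.isnan(row["mismatch_to_perfect"])  # undefined, not infinite


# ------------------------------------------------------------ k-mers


def naive_kmer_count(genome, probe, both_strands=True):
    rc = reverse_complement(probe)
    count = 0
    for seq in genome.values():
        for i in range(len(seq) - len(probe) + 1):
            w = seq[i : i + len(probe)]
            if any(c not in "ACGT" for c in w):
                continue
            if w == probe or (both_strands and rc != probe and w == rc):
                count += 1
    return count


def _probe_df(seqs):
    return pd.DataFrame(
        {"probe_id": [f"p{i}" for i in range(len(seqs))], "sequence": seqs}
    )


def test_absent_probe_counts_zero():
    res = kmer_frequency({"g": "AAAATTTT"}, _probe_df(["CCCC"]))
    assert res.loc[0, "count_in_genome"] == 0


def test_overlapping_and_palindrome_counting():
    # genome AAAA, probe AA: 3 forward windows; RC "TT" absent → 3
    res = kmer_frequency({"g": "AAAA"}, _probe_df(["AA"]))
    assert res.loc[0, "count_in_genome"] == 3
    # probe AT is its own reverse complement: windows counted once
    res2 = kmer_frequency({"g": "ATAT"}, _probe_df(["AT"]))
    assert res2.loc[0, "count_in_genome"] == 2


def test_reverse_complement_counted():
    res = kmer_frequency({"g": "TTTTT"}, _probe_df(["AAAA"]))
    assert res.loc[0, "count_in_genome"] == 2  # two windows of RC TTTT


def test_probe_drawn_from_genome_counts_at_least_once(rng):
    genome = random_dna(rng, 2000)
    probe = genome[100:125]
    res = kmer_frequency({"g": genome}, _probe_df([probe]))
    assert res.loc[0, "count_in_genome"] >= 1


def test_matches_naive_scan_with_planted_duplications(rng):
    core = random_dna(rng, 3000)
    dup = core[500:525]
    genome = {"chr1": core + dup * 3, "chr2": random_dna(rng, 1000)}
    probes = _probe_df([dup, core[0:25], random_dna(rng, 25)])
    res = kmer_frequency(genome, probes)
    for i, row in res.iterrows():
        assert row["count_in_genome"] == naive_kmer_count(
            genome, probes.loc[i, "sequence"]
        )
    single = kmer_frequency(genome, probes, both_strands=False)
    for i, row in single.iterrows():
        assert row["count_in_genome"] == naive_kmer_count(
            genome, probes.loc[i, "sequence"], both_strands=False
        )


def test_ambiguous_genome_windows_skipped():
    res = kmer_frequency({"g": "AANAA"}, _probe_df(["AA"]))
    assert res.loc[0, "count_in_genome"] == 2


def test_ambiguous_probe_rejected():
    with pytest.raises(ValueError):
        kmer_frequency({"g": "ACGT"}, _probe_df(["ANGT"]))
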