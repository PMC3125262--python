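"""Evaluation procedures: conserved-gene calling, deletion ratio scans,
probe-identity specificity curves, and genome k-mer frequency.

Three questions about a cross-species hybridization are answered here:

* **Conservation** — which genes have exon probes whose mean adjusted
  intensity is significantly greater than zero (one-sample, one-sided
  t-test per gene, Bonferroni-corrected family-wise)?
* **Sensitivity** — does the ratio track between two hybridizations of
  the same array dip below 1.0 over a genuine deletion, and can such
  dips be called automatically (windowed-median run scan)?
* **Specificity** — when probes are classified by their true nucleotide
  identity to the ortholog (false <23 of 25, semi-true 23–24, true 25),
  how do false and true matches accumulate as the intensity-ratio
  threshold is lowered, and what is the ratio of mismatch (<25 nt) to
  perfect-match probes at each threshold?
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from Bio import Align

__all__ = [
    "conserved_gene_test",
    "ratio_track",
    "deletion_scan",
    "align_orthologs",
    "probe_identity",
    "classify_matches",
    "threshold_accumulation",
    "matched_tp_mismatch_ratio",
    "kmer_frequency",
    "reverse_complement",
]

from .thermo import reverse_complement


# ---------------------------------------------------------------- conserved


def conserved_gene_test(
    ai: pd.DataFrame,
    probes: pd.DataFrame,
    alpha_fw: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-gene test that mean exon-probe adjusted intensity exceeds zero.

    Parameters
    ----------
    ai
        Adjusted intensities for one species (``probe_id``, ``ai``).
    probes
        Probe annotation; only rows with ``region == "exon"`` and a
        ``gene_id`` are used.  Genes with fewer than 2 exon probes with
        AI values are excluded (not an error).
    alpha_fw
        Family-wise level; each gene is called significant when its raw
        one-sided p-value is ≤ alpha_fw / (number of genes tested)
        (Bonferroni).
    alternative
        ``"greater"`` (default; conservation means signal above the
        non-specific baseline) or ``"two-sided"``.

    Returns one row per tested gene, sorted by ``gene_id``, with columns
    ``gene_id, n_exon_probes, mean_ai, t_stat, p_raw, significant``.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    exon = probes.loc[
        (probes["region"] == "exon") & probes["gene_id"].notna(),
        ["probe_id", "gene_id"],
    ]
    merged = exon.merge(ai[["probe_id", "ai"]], on="probe_id", how="inner")
    g = merged.groupby("gene_id", sort=True)["ai"]
    stats = g.agg(n_exon_probes="count", mean_ai="mean", sd="std")
    stats = stats[stats["n_exon_probes"] >= 2]
    n = stats["n_exon_probes"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # sd == 0 yields t = ±inf (nonzero mean) or NaN (all-zero gene)
        t = stats["mean_ai"].to_numpy() / (stats["sd"].to_numpy() / np.sqrt(n))
    if alternative == "greater":
        p = scipy.stats.t.sf(t, df=n - 1)
    else:
        p = 2 * scipy.stats.t.sf(np.abs(t), df=n - 1)
    out = pd.DataFrame(
        {
            "gene_id": stats.index,
            "n_exon_probes": stats["n_exon_probes"].to_numpy(),
            "mean_ai": stats["mean_ai"].to_numpy(),
            "t_stat": t,
            "p_raw": p,
        }
    )
    n_tested = len(out)
    out["significant"] = out["p_raw"] <= (alpha_fw / n_tested if n_tested else np.nan)
    return out.sort_values("gene_id", ignore_index=True)


# ---------------------------------------------------------------- ratio scan


def ratio_track(
    test: pd.DataFrame,
    reference: pd.DataFrame,
    probes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-probe intensity ratio of a test over a reference species.

    AI values are log-scale, so the ratio back-transforms to
    ``exp(ai_test - ai_reference)``; a probe binding equally in both
    species sits at 1.0.  Probes present in only one AI table are
    excluded.  Output is sorted by chromosome then position with columns
    ``probe_id, chromosome, position, ratio``.
    """
    merged = test[["probe_id", "ai"]].merge(
        reference[["probe_id", "ai"]], on="probe_id", suffixes=("_test", "_ref")
    )
    merged = merged.merge(
        probes[["probe_id", "chromosome", "start"]], on="probe_id", how="inner"
    )
    merged["ratio"] = np.exp(merged["ai_test"] - merged["ai_ref"])
    out = merged.rename(columns={"start": "position"})[
        ["probe_id", "chromosome", "position", "ratio"]
    ]
    return out.sort_values(["chromosome", "position"], ignore_index=True)


def deletion_scan(
    track: pd.DataFrame,
    window_probes: int = 5,
    ratio_threshold: float = 0.5,
    min_run: int = 10,
    probe_length: int = 25,
) -> pd.DataFrame:
    """Call candidate deletions as runs of suppressed ratio.

    Within each chromosome, each probe's ratio is replaced by the median
    over a centered window of ``window_probes`` probes; maximal runs of
    at least ``min_run`` consecutive probes whose windowed median falls
    below ``ratio_threshold`` are reported as half-open genomic
    intervals ``[first probe start, last probe start + probe_length)``
    with the run's raw mean ratio and probe count.
    """
    if window_probes < 1:
        raise ValueError("window_probes must be ≥ 1")
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    rows = []
    for chrom, grp in track.groupby("chromosome", sort=True):
        grp = grp.sort_values("position")
        ratios = grp["ratio"].to_numpy(dtype=float)
        pos = grp["position"].to_numpy()
        med = (
            pd.Series(ratios)
            .rolling(window_probes, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        below = med < ratio_threshold
        # maximal runs of consecutive True
        idx = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
        for start, stop in zip(idx[::2], idx[1::2]):
            if stop - start >= min_run:
                rows.append(
                    {
                        "chromosome": chrom,
                        "start": int(pos[start]),
                        "end": int(pos[stop - 1]) + probe_length,
                        "n_probes": int(stop - start),
                        "mean_ratio": float(ratios[start:stop].mean()),
                    }
                )
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "n_probes", "mean_ratio"]
    )


# ------------------------------------------------------------- specificity


def align_orthologs(a: str, b: str) -> tuple[str, str, float]:
    """Global pairwise alignment of two ortholog sequences.

    Scoring: match +1, mismatch −1, gap open −5, gap extend −1 (a gap of
    length L costs 5 + (L−1)).  Returns the gapped sequences and the
    optimal score; when several alignments are co-optimal the first in
    the aligner's deterministic enumeration order is returned.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-1,
    )
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, float(aln.score)


def classify_matches(
    matches: int, probe_length: int = 25, semi_min: int = 23
) -> str:
    """Identity class of a probe: ``true`` (perfect), ``semi-true``
    (within 2 of perfect by default), else ``false``.

    With 25-mers and the default boundary, false is <23 matches
    (including 22), semi-true 23–24, true 25.
    """
    if matches > probe_length:
        raise ValueError("matches cannot exceed probe length")
    if matches == probe_length:
        return "true"
    if matches >= semi_min:
        return "semi-true"
    return "false"


def probe_identity(
    alignment: tuple[str, str],
    probe_starts: Sequence[int],
    probe_length: int = 25,
    probe_ids: Sequence | None = None,
    semi_min: int = 23,
) -> pd.DataFrame:
    """Nucleotide identity of each probe against the aligned ortholog.

    ``alignment`` is (gapped reference, gapped ortholog); probe offsets
    are 0-based positions in the *ungapped* reference.  A probe's match
    count is the number of alignment columns within its span where both
    sequences carry the identical nucleotide; gap columns count as
    mismatch.  Returns ``probe_id, matches, identity_class``.
    """
    ref_g, alt_g = alignment
    if len(ref_g) != len(alt_g):
        raise ValueError("gapped sequences differ in length")
    ref_arr = np.frombuffer(ref_g.encode(), dtype="S1")
    alt_arr = np.frombuffer(alt_g.encode(), dtype="S1")
    is_ref = ref_arr != b"-"
    ref_len = int(is_ref.sum())
    # alignment column index of each ungapped reference position
    col_of = np.flatnonzero(is_ref)
    match_col = (ref_arr == alt_arr) & is_ref & (alt_arr != b"-")
    cmatch = np.concatenate([[0], np.cumsum(match_col.view(np.int8))])
    rows = []
    ids = probe_ids if probe_ids is not None else list(range(len(probe_starts)))
    for pid, s in zip(ids, probe_starts):
        if s < 0 or s + probe_length > ref_len:
            raise ValueError(f"probe {pid!r} span exceeds the ungapped reference")
        c0, c1 = col_of[s], col_of[s + probe_length - 1] + 1
        m = int(cmatch[c1] - cmatch[c0])
        rows.append(
            {
                "probe_id": pid,
                "matches": m,
                "identity_class": classify_matches(m, probe_length, semi_min),
            }
        )
    return pd.DataFrame(rows, columns=["probe_id", "matches", "identity_class"])


def threshold_accumulation(
    ratios: Mapping | pd.Series,
    identities: pd.DataFrame,
    thresholds: Iterable[float],
    probe_length: int = 25,
) -> pd.DataFrame:
    """Accumulation of probe matches by identity class over ratio thresholds.

    For each threshold t, counts probes with intensity ratio ≥ t in each
    identity class, plus the ratio of mismatch probes (<probe_length
    identical nt) to perfect-match probes at-or-above t
    (``mismatch_to_perfect``, NaN when no perfect probe clears t).
    Counts are non-increasing in the threshold.
    """
    ratios = pd.Series(ratios)
    df = identities.merge(
        ratios.rename("ratio"), left_on="probe_id", right_index=True, how="inner"
    )
    rows = []
    for t in thresholds:
        sel = df[df["ratio"] >= t]
        n_true = int((sel["matches"] == probe_length).sum())
        n_semi = int((sel["identity_class"] == "semi-true").sum())
        n_false = int((sel["identity_class"] == "false").sum())
        n_mismatch = int((sel["matches"] < probe_length).sum())
        rows.append(
            {
                "threshold": float(t),
                "n_true": n_true,
                "n_semi_true": n_semi,
                "n_false": n_false,
                "mismatch_to_perfect": (n_mismatch / n_true) if n_true else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["threshold", "n_true", "n_semi_true", "n_false", "mismatch_to_perfect"],
    )


def matched_tp_mismatch_ratio(
    curve: pd.DataFrame, tp_count: int
) -> tuple[float, float]:
    """Highest threshold detecting at least ``tp_count`` true positives,
    and the mismatch-to-perfect ratio there.

    This is how two normalizations on incommensurable scales are
    compared: fix the true-positive yield and ask how many mismatch
    probes each method drags along.
    """
    ok = curve[curve["n_true"] >= tp_count]
    if ok.empty:
        raise ValueError(f"no threshold reaches {tp_count} true positives")
    row = ok.loc[ok["threshold"].idxmax()]
    return float(row["threshold"]), float(row["mismatch_to_perfect"])


# ---------------------------------------------------------------- k-mers


def kmer_frequency(
    genome: Mapping[str, str],
    probes: pd.DataFrame,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Exact occurrence count of each probe sequence in a genome.

    Counts windows of the genome equal to the probe sequence or (by
    default) its reverse complement, overlaps included, summed over all
    genome sequences.  A window matching both orientations (a reverse-
    complement palindrome) is counted once.  Windows containing
    ambiguous bases are skipped.  Returns ``probe_id, count_in_genome``.
    """
    seqs = probes["sequence"].str.upper()
    bad = seqs[~seqs.str.fullmatch("[ACGT]+")]
    if len(bad):
        raise ValueError(
            "ambiguous probe sequence(s): " + ", ".join(map(str, bad.index[:10]))
        )
    counts: dict[int, dict[str, int]] = {}
    for k in sorted(set(seqs.str.len())):
        table: dict[str, int] = {}
        for name, chrom_seq in genome.items():
            chrom_seq = chrom_seq.upper()
            for i in range(len(chrom_seq) - k + 1):
                w = chrom_seq[i : i + k]
                if "ACGT".find(w[0]) >= 0 and all(c in "ACGT" for c in w):
                    table[w] = table.get(w, 0) + 1
        counts[k] = table
    out = []
    for pid, s in zip(probes["probe_id"], seqs):
        table = counts[len(s)]
        n = table.get(s, 0)
        if both_strands:
            rc = reverse_complement(s)
            if rc != s:
                n += table.get(rc, 0)
        out.append({"probe_id": pid, "count_in_genome": n})
    return pd.DataFrame(out, columns=["probe_id", "count_in_genome"])
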