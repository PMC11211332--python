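"""Interval overlap, peak-set Jaccard, hypergeometric enrichment,
peak-to-gene annotation, and signature scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tcrlineage import (
    annotate_peaks_to_genes,
    atac_signature_score,
    hypergeometric_enrichment,
    overlap_peaks,
    peakset_jaccard,
    zscore_cluster_means,
)
from tcrlineage.scoring import read_bed


def peaks(intervals, chrom="chr1"):
    return pd.DataFrame(
        [
            {"chrom": c[0] if len(c) == 3 else chrom, "start": c[-2], "end": c[-1], "id": f"p{i}"}
            for i, c in enumerate(intervals)
        ]
    )


def test_one_base_overlap_counts():
    flags, n = overlap_peaks(peaks([(100, 200)]), peaks([(199, 300)]))
    assert flags.all() and n == 1


def test_half_open_abutment_is_not_overlap():
    flags, n = overlap_peaks(peaks([(100, 200)]), peaks([(200, 300)]))
    assert not flags.any() and n == 0


def test_chromosomes_do_not_cross_match():
    q = peaks([("chr1", 0, 100)])
    s = peaks([("chr2", 0, 100)])
    _, n = overlap_peaks(q, s)
    assert n == 0


def test_overlap_matches_brute_force_on_random_intervals():
    rng = np.random.default_rng(77)
    chroms = ["chr1", "chr2", "chr3"]
    def random_peaks(n):
        starts = rng.integers(0, 5000, size=n)
        return pd.DataFrame(
            {
                "chrom": rng.choice(chroms, size=n),
                "start": starts,
                "end": starts + rng.integers(1, 300, size=n),
                "id": [f"i{k}" for k in range(n)],
            }
        )
    q, s = random_peaks(1000), random_peaks(1000)
    flags, _ = overlap_peaks(q, s)
    # O(n^2) scan: half-open intervals overlap iff start < other_end both ways
    expected = [
        any(
            qc == sc and qs < se and ss < qe
            for sc, ss, se in zip(s["chrom"], s["start"], s["end"])
        )
        for qc, qs, qe in zip(q["chrom"], q["start"], q["end"])
    ]
    assert flags.tolist() == expected


def test_peakset_jaccard_values():
    a = peaks([(0, 10), (20, 30), (40, 50)])
    assert peakset_jaccard(a, a) == 1.0
    b = peaks([(100, 110)])
    assert peakset_jaccard(a, b) == 0.0
    # 3 query intervals, 4 subject intervals, 2 hits -> 2 / (3 + 4 - 2)
    subject = peaks([(0, 10), (25, 28), (100, 110), (200, 210)])
    assert peakset_jaccard(a, subject) == pytest.approx(2 / 5)


def test_peakset_jaccard_empty_sets():
    empty = peaks([])
    assert peakset_jaccard(empty, empty) == 0.0
    assert peakset_jaccard(peaks([(0, 5)]), pd.DataFrame(columns=["chrom", "start", "end", "id"])) == 0.0


def test_hypergeometric_exhaustive_enumeration():
    """Upper-tail p equals exhaustive enumeration over all draws, N <= 12."""
    assert hypergeometric_enrichment(0, 4, 5, 10) == pytest.approx(1.0)
    assert hypergeometric_enrichment(4, 4, 5, 10) == pytest.approx(5 / 210)
    rng = np.random.default_rng(5)
    for _ in range(20):
        N = int(rng.integers(2, 13))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        # enumerate all C(N, n) draws from a universe with K successes
        universe = [1] * K + [0] * (N - K)
        draws = list(itertools.combinations(range(N), n))
        p_enum = sum(1 for d in draws if sum(universe[i] for i in d) >= k) / len(draws)
        assert hypergeometric_enrichment(k, n, K, N) == pytest.approx(p_enum)


def test_hypergeometric_cross_implementation():
    """Matches 1 - CDF(k-1) from direct binomial-coefficient arithmetic."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        N = int(rng.integers(5, 500))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        p_direct = sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
        ) / math.comb(N, n)
        assert hypergeometric_enrichment(k, n, K, N) == pytest.approx(p_direct, rel=1e-9)


def test_hypergeometric_monotone_in_k():
    ps = [hypergeometric_enrichment(k, 20, 30, 100) for k in range(0, 21)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.mark.parametrize("bad", [(5, 4, 5, 10), (2, 4, 11, 10), (2, 11, 5, 10), (-1, 4, 5, 10)])
def test_hypergeometric_domain_errors(bad):
    with pytest.raises(ValueError):
        hypergeometric_enrichment(*bad)


def features(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "feature_type", "gene"])


def test_peak_annotation_window():
    feats = features([("chr1", 10000, "+", "TSS", "GENE1")])
    near = peaks([(5001, 5101)])  # nearest edge 4,900 bp upstream of the TSS at 10,000
    ann = annotate_peaks_to_genes(near, feats)
    assert ann.loc[0, "gene"] == "GENE1"
    assert ann.loc[0, "distance"] == 4900
    far = peaks([(0, 4999)])  # nearest edge at 4,998 -> 5,002 bp away
    ann_far = annotate_peaks_to_genes(far, feats)
    assert pd.isna(ann_far.loc[0, "gene"])


def test_peak_annotation_exact_window_edges():
    feats = features([("chr1", 10000, "-", "TSS", "G")])
    assert annotate_peaks_to_genes(peaks([(4999, 5001)]), feats).loc[0, "gene"] == "G"  # 5,000 away
    assert pd.isna(annotate_peaks_to_genes(peaks([(4998, 4999)]), feats).loc[0, "gene"])  # 5,002 away


def test_peak_annotation_requires_strand():
    feats = features([("chr1", 100, None, "TSS", "G")])
    with pytest.raises(ValueError, match="strand"):
        annotate_peaks_to_genes(peaks([(0, 50)]), feats)


def test_peak_annotation_matches_brute_force():
    rng = np.random.default_rng(3)
    n_feat = 40
    feats = features(
        [
            (rng.choice(["chr1", "chr2"]), int(rng.integers(0, 200000)), "+",
             rng.choice(["TSS", "miRNA", "exon"]), f"G{i}")
            for i in range(n_feat)
        ]
    )
    starts = rng.integers(0, 200000, size=200)
    pk = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=200),
            "start": starts,
            "end": starts + rng.integers(1, 1000, size=200),
            "id": [f"p{i}" for i in range(200)],
        }
    )
    ann = annotate_peaks_to_genes(pk, feats, window=5000)
    for row, (_, peak) in zip(ann.itertuples(), pk.iterrows()):
        best_gene, best_d = None, None
        for _, f in feats.iterrows():
            if f["chrom"] != peak["chrom"]:
                continue
            d = max(peak["start"] - f["pos"], f["pos"] - (peak["end"] - 1), 0)
            if d <= 5000 and (best_d is None or d < best_d):
                best_gene, best_d = f["gene"], d
        if best_gene is None:
            assert pd.isna(row.gene)
        else:
            assert row.distance == best_d  # ties may pick either feature at equal distance


def test_read_bed_half_open(tmp_path):
    bed = tmp_path / "peaks.bed"
    bed.write_text("chr1\t100\t200\tpeakA\nchr2\t0\t50\n")
    df = read_bed(bed)
    assert df.loc[0, "id"] == "peakA"
    assert df.loc[1, "id"] == "chr2:0-50"
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t200\t200\n")
    with pytest.raises(ValueError):
        read_bed(bad)


def matrix(values, samples, genes):
    return pd.DataFrame(values, index=samples, columns=genes)


def test_signature_score_single_gene_and_constant():
    m = matrix([[1.0, 2.0], [3.0, 4.0]], ["s1", "s2"], ["g1", "g2"])
    score = atac_signature_score(m, ["g2"])
    assert score.tolist() == [2.0, 4.0]
    const = matrix(np.full((3, 4), 7.0), ["a", "b", "c"], list("wxyz"))
    assert atac_signature_score(const, ["w", "x", "y"]).tolist() == [7.0] * 3


def test_signature_score_matches_row_means():
    rng = np.random.default_rng(1)
    m = matrix(rng.normal(size=(6, 20)), [f"s{i}" for i in range(6)], [f"g{i}" for i in range(20)])
    gene_list = ["g3", "g7", "g11", "g15", "g19"]
    score = atac_signature_score(m, gene_list)
    expected = m[gene_list].to_numpy().mean(axis=1)
    assert np.allclose(score.to_numpy(), expected)
    # invariant to gene-list and sample ordering
    score_rev = atac_signature_score(m.iloc[::-1], gene_list[::-1])
    assert np.allclose(score_rev.to_numpy(), expected[::-1])
    total = atac_signature_score(m, gene_list, aggregation="sum")
    assert np.allclose(total.to_numpy(), expected * len(gene_list))


def test_signature_score_missing_genes(caplog):
    m = matrix([[1.0, 2.0]], ["s1"], ["g1", "g2"])
    with caplog.at_level("WARNING"):
        score = atac_signature_score(m, ["g1", "nope"])
    assert score.tolist() == [1.0]
    with pytest.raises(ValueError):
        atac_signature_score(m, ["nope"])


def test_zscore_cluster_means_hand_computed():
    expr = pd.DataFrame(
        {
            "gA": [1.0, 1.0, 2.0, 2.0, 6.0, 6.0],
            "gB": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
        }
    )
    labels = ["c1", "c1", "c2", "c2", "c3", "c3"]
    z, flags = zscore_cluster_means(expr, labels)
    means = np.array([1.0, 2.0, 6.0])
    expected = (means - means.mean()) / means.std(ddof=1)
    assert np.allclose(z.loc["gA"].to_numpy(), expected)
    assert flags["gB"] and not flags["gA"]
    assert (z.loc["gB"] == 0).all()
    # z-scored rows have mean 0, unit variance
    assert abs(z.loc["gA"].mean()) < 1e-9
    assert abs(z.loc["gA"].var(ddof=1) - 1) < 1e-9


def test_zscore_marker_peaks_in_its_cluster():
    rng = np.random.default_rng(8)
    labels = [f"c{i % 4}" for i in range(40)]
    expr = pd.DataFrame({"marker": [5.0 if lab == "c2" else rng.normal() for lab in labels]})
    z, _ = zscore_cluster_means(expr, labels)
    assert z.loc["marker"].idxmax() == "c2"
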