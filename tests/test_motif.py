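import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sibflow import motif, syndata
from sibflow.motif import (
    PWM,
    MotifHit,
    RegionConfig,
    combined_zscore,
    dedup_hits,
    ets_signature,
    extract_regions,
    opossum_zscore,
    peak_gene_tally,
    pwm_score_threshold,
    revcomp,
    scan,
)


def _enum_tail(pwm: PWM, granularity: float) -> dict[int, float]:
    """Exhaustive tail probabilities of discretized scores (oracle)."""
    S = np.round(pwm.log_odds / granularity).astype(np.int64)
    L = pwm.length
    bg = pwm.background
    probs: dict[int, float] = {}
    for bases in itertools.product(range(4), repeat=L):
        s = int(S[list(bases), range(L)].sum())
        p = float(np.prod([bg[b] for b in bases]))
        probs[s] = probs.get(s, 0.0) + p
    tail, cum = {}, 0.0
    for s in sorted(probs, reverse=True):
        cum += probs[s]
        tail[s] = cum
    return tail


class TestPWM:
    def test_consensus_relative_score_is_one(self, ets_pwm):
        assert ets_pwm.relative(ets_pwm.max_score) == pytest.approx(1.0)

    def test_four_rows_required(self):
        with pytest.raises(ValueError):
            PWM.from_counts("bad", np.ones((3, 5)))

    def test_background_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM.from_counts("bad", np.ones((4, 3)), background=np.array([0.5, 0.5, 0.5, 0.5]))

    def test_reverse_complement_scores_revcomp_sequences(self, ets_pwm):
        rc = ets_pwm.reverse_complement()
        seq = ets_pwm.consensus
        fwd = sum(
            ets_pwm.log_odds[motif._BASE_IDX[b], i] for i, b in enumerate(seq)
        )
        rev = sum(
            rc.log_odds[motif._BASE_IDX[b], i] for i, b in enumerate(revcomp(seq))
        )
        assert fwd == pytest.approx(rev)

    def test_jaspar_round_trip(self, tmp_path):
        from sibflow import io as sio

        mats = syndata.default_pwms()
        path = tmp_path / "m.jaspar"
        sio.write_jaspar(str(path), mats)
        pwms = motif.read_jaspar(str(path))
        assert len(pwms) == 2
        ets = next(p for n, p in pwms.items() if "ETSLIKE" in n)
        ref = PWM.from_counts("ETSLIKE", mats["ETSLIKE"])
        np.testing.assert_allclose(ets.log_odds, ref.log_odds, atol=1e-12)


class TestScoreThreshold:
    @pytest.mark.parametrize("bg", [None, np.array([0.4, 0.1, 0.1, 0.4])])
    @pytest.mark.parametrize("length", [3, 4, 5, 6])
    def test_dp_equals_enumeration(self, ctrl_pwm, bg, length):
        counts = syndata.default_pwms()["CTRLMOTIF"][:, :length]
        pwm = PWM.from_counts("sub", counts, background=bg)
        gran = 1e-4
        tail = _enum_tail(pwm, gran)
        for p in (0.5, 0.1, 0.01, 0.001):
            thr = pwm_score_threshold(pwm, p, granularity=gran)
            thr_int = int(round(thr / gran))
            # tail at or above the returned threshold must be <= p ...
            mass_at_or_above = _tail_at(tail, thr_int)
            assert mass_at_or_above <= p + 1e-12
            # ... and one grid step lower must exceed p (tightness)
            assert _tail_at(tail, thr_int - 1) > p

    def test_degenerate_equal_columns(self):
        counts = np.ones((4, 2))
        pwm = PWM.from_counts("flat", counts)
        thr = pwm_score_threshold(pwm, 0.5)
        # single attainable score: it has tail 1.0 > 0.5, so the threshold
        # sits above it and admits nothing
        assert thr > pwm.max_score

    def test_threshold_monotone_in_p(self, ets_pwm):
        ps = [0.5, 0.1, 0.01, 0.001]
        thrs = [pwm_score_threshold(ets_pwm, p) for p in ps]
        assert all(t2 >= t1 for t1, t2 in zip(thrs, thrs[1:]))

    def test_invalid_p(self, ets_pwm):
        with pytest.raises(ValueError):
            pwm_score_threshold(ets_pwm, 0.0)


def _tail_at(tail: dict[int, float], s: int) -> float:
    """P(score >= s) from an observed-score tail table."""
    above = [k for k in tail if k >= s]
    return tail[min(above)] if above else 0.0


class TestScan:
    def test_consensus_hit(self, ets_pwm):
        hits = scan({"s": ets_pwm.consensus}, ets_pwm, rel_threshold=0.99)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].start == 0
        assert fwd[0].rel_score == pytest.approx(1.0)

    def test_revcomp_hit_on_minus_strand(self, ets_pwm):
        seq = revcomp(ets_pwm.consensus)
        hits = scan({"s": seq}, ets_pwm, rel_threshold=0.99)
        rev = [h for h in hits if h.strand == "-"]
        assert len(rev) == 1
        assert rev[0].score == pytest.approx(ets_pwm.max_score)

    def test_matches_exhaustive_window_scoring(self, ets_pwm, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        thr = 0.75
        hits = scan({"s": seq}, ets_pwm, rel_threshold=thr)
        L = ets_pwm.length
        expected = []
        for start in range(len(seq) - L + 1):
            for strand, window in (
                ("+", seq[start : start + L]),
                ("-", revcomp(seq[start : start + L])),
            ):
                raw = sum(
                    ets_pwm.log_odds[motif._BASE_IDX[b], i]
                    for i, b in enumerate(window)
                )
                if ets_pwm.relative(raw) >= thr:
                    expected.append((start, strand, round(raw, 9)))
        got = [(h.start, h.strand, round(h.score, 9)) for h in hits]
        assert got == sorted(expected)

    def test_n_windows_skipped(self, ets_pwm):
        seq = ets_pwm.consensus[:4] + "N" + ets_pwm.consensus[5:]
        hits = scan({"s": seq}, ets_pwm, rel_threshold=0.0)
        assert hits == []

    def test_short_sequence_no_hits(self, ets_pwm):
        assert scan({"s": "ACG"}, ets_pwm) == []

    def test_strand_invariance_of_counts(self, ets_pwm, rng):
        seqs = {
            f"s{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 200))
            for i in range(5)
        }
        rc = {k: revcomp(v) for k, v in seqs.items()}
        h1 = scan(seqs, ets_pwm, rel_threshold=0.8)
        h2 = scan(rc, ets_pwm, rel_threshold=0.8)
        assert len(h1) == len(h2)

    def test_pvalue_mode_admits_consensus(self, ets_pwm):
        hits = scan({"s": ets_pwm.consensus}, ets_pwm, mode="pvalue", pvalue=0.001)
        assert any(h.strand == "+" and h.start == 0 for h in hits)


class TestDedup:
    def _hit(self, start, score, strand="+", pwm="X"):
        return MotifHit("s", start, strand, score, 0.9, pwm, 6)

    def test_best_within_window_kept(self):
        kept = dedup_hits([self._hit(0, 5.0), self._hit(1, 7.0)], window=3)
        assert len(kept) == 1
        assert kept[0].score == 7.0

    def test_far_apart_both_kept(self):
        kept = dedup_hits([self._hit(0, 5.0), self._hit(5, 7.0)], window=3)
        assert len(kept) == 2

    def test_idempotent(self, rng):
        hits = [
            self._hit(int(s), float(sc), pwm=p)
            for s, sc, p in zip(
                rng.integers(0, 50, 30), rng.uniform(1, 10, 30), ["A", "B"] * 15
            )
        ]
        once = dedup_hits(hits)
        twice = dedup_hits(once)
        assert [
            (h.start, h.strand, h.score) for h in once
        ] == [(h.start, h.strand, h.score) for h in twice]

    def test_tie_breaks_to_lower_start_forward(self):
        kept = dedup_hits(
            [self._hit(2, 5.0, "-"), self._hit(1, 5.0, "+")], window=3
        )
        assert len(kept) == 1
        assert (kept[0].start, kept[0].strand) == (1, "+")

    def test_applies_across_matrices(self):
        kept = dedup_hits(
            [self._hit(0, 5.0, pwm="ETS1"), self._hit(1, 6.0, pwm="ELK1")],
            window=3,
        )
        assert len(kept) == 1
        assert kept[0].pwm == "ELK1"


class TestZScore:
    def test_formula_oracle(self):
        # direct formula evaluation: t=20, T=1e4, b=50, B=1e5
        rate = 50 / 100_000
        mu = rate * 10_000
        sigma = math.sqrt(10_000 * rate * (1 - rate))
        expected = (20 - mu) / sigma
        res = motif.EnrichmentResult(
            "x", 20, 10_000, 50, 100_000, rate, mu, sigma, (20 - mu) / sigma
        )
        assert res.z == pytest.approx(expected)
        assert mu == pytest.approx(5.0)
        assert expected == pytest.approx(15 / math.sqrt(4.9975))

    def test_identical_sets_z_zero(self, ets_pwm, rng):
        seqs = {
            f"s{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 500))
            for i in range(10)
        }
        res = opossum_zscore(seqs, dict(seqs), ets_pwm)
        if res.z is not None:
            assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_planted_enrichment_positive_depletion_negative(self, ets_pwm):
        dense, _ = syndata.simulate_promoters(
            {"s": [f"d{i}" for i in range(30)]}, ets_pwm, {"s": 5.0}, 1000, seed=1
        )
        sparse, _ = syndata.simulate_promoters(
            {"s": [f"p{i}" for i in range(30)]}, ets_pwm, {"s": 0.5}, 1000, seed=2
        )
        assert opossum_zscore(dense, sparse, ets_pwm).z > 3
        assert opossum_zscore(sparse, dense, ets_pwm).z < -3

    def test_empty_set_rejected(self, ets_pwm):
        with pytest.raises(ValueError):
            opossum_zscore({}, {"a": "ACGT"}, ets_pwm)

    def test_sigma_zero_flagged(self, ets_pwm):
        # control with zero hits -> rate 0 -> sigma 0 -> undefined z
        res = opossum_zscore(
            {"t": ets_pwm.consensus * 3}, {"c": "A" * 50}, ets_pwm
        )
        assert res.z is None
        assert res.flagged


class TestCombinedZ:
    def test_mean(self):
        z, single = combined_zscore(2.0, 4.0)
        assert z == 3.0
        assert not single

    def test_single_source_flagged(self):
        z, single = combined_zscore(2.5, None)
        assert z == 2.5
        assert single

    def test_symmetric(self):
        assert combined_zscore(1.0, 5.0)[0] == combined_zscore(5.0, 1.0)[0]

    def test_both_missing(self):
        z, flagged = combined_zscore(None, None)
        assert z is None and flagged


class TestExtractRegions:
    def _setup(self):
        genome = {"chr1": "".join("ACGT"[(i * 7) % 4] for i in range(4000))}
        models = pd.DataFrame(
            [
                ("plus", "chr1", 2000, 2400, "+"),
                ("minus", "chr1", 500, 1000, "-"),
                ("edge", "chr1", 300, 700, "+"),
            ],
            columns=["gene", "contig", "start", "end", "strand"],
        )
        return genome, models

    def test_plus_strand_window(self):
        genome, models = self._setup()
        up, _, _ = extract_regions(models, genome, None, gene_ids=["plus"])
        assert up["plus"] == genome["chr1"][500:2000]

    def test_minus_strand_window_revcomped(self):
        genome, models = self._setup()
        up, _, _ = extract_regions(models, genome, None, gene_ids=["minus"])
        assert up["minus"] == revcomp(genome["chr1"][1000:2500])

    def test_clamped_at_contig_start(self):
        genome, models = self._setup()
        with pytest.warns(UserWarning, match="clamped"):
            up, _, _ = extract_regions(models, genome, None, gene_ids=["edge"])
        assert up["edge"] == genome["chr1"][0:300]

    def test_whole_overlapping_peak_kept(self):
        genome, models = self._setup()
        peaks = pd.DataFrame(
            [("chr1", 450, 620, "pk")], columns=["contig", "start", "end", "name"]
        )
        _, atac, _ = extract_regions(models, genome, peaks, gene_ids=["plus"])
        (key,) = atac.keys()
        assert atac[key] == genome["chr1"][450:620]  # whole peak, not clipped

    def test_missing_gene_skipped(self):
        genome, models = self._setup()
        up, _, skipped = extract_regions(models, genome, None, gene_ids=["ghost", "plus"])
        assert skipped == ["ghost"]
        assert "plus" in up


class TestEtsSignature:
    def test_identical_rows_adjacent(self, rng):
        base = rng.normal(size=4)
        rows = np.vstack([rng.normal(size=(3, 4)) * 3, base, base])
        var = pd.DataFrame(
            rows, index=[f"b{i}" for i in range(5)],
            columns=["by_sibs", "enr1", "enr2", "elk"],
        )
        ordered, Z, missing = ets_signature(var)
        idx = list(ordered.index)
        assert abs(idx.index("b3") - idx.index("b4")) == 1
        assert missing == []

    def test_linkage_matches_brute_force_average(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        X = rng.normal(size=(4, 4))
        var = pd.DataFrame(X, index=list("abcd"), columns=["w", "x", "y", "z"])
        _, Z, _ = ets_signature(var)
        ref = linkage(pdist(X), method="average")
        np.testing.assert_allclose(Z, ref)

    def test_missing_rows_excluded_and_listed(self, rng):
        X = rng.normal(size=(4, 4))
        var = pd.DataFrame(X, index=list("abcd"), columns=["w", "x", "y", "z"])
        var.loc["c", "x"] = np.nan
        ordered, _, missing = ets_signature(var)
        assert missing == ["c"]
        assert list(ordered.index)[-1] == "c"  # retained, appended at the end

    def test_planted_direct_vs_relay_split(self, rng):
        direct = np.column_stack(
            [rng.normal(5, 0.3, 6), rng.normal(4, 0.3, 6), rng.normal(0, 0.3, 6), rng.normal(2, 0.2, 6)]
        )
        relay = np.column_stack(
            [rng.normal(0, 0.3, 6), rng.normal(0, 0.3, 6), rng.normal(0, 0.3, 6), rng.normal(0, 0.2, 6)]
        )
        var = pd.DataFrame(
            np.vstack([direct, relay]),
            index=[f"d{i}" for i in range(6)] + [f"r{i}" for i in range(6)],
            columns=["by_sibs", "enr1", "enr2", "elk"],
        )
        ordered, Z, _ = ets_signature(var)
        from scipy.cluster.hierarchy import fcluster

        top2 = fcluster(Z, t=2, criterion="maxclust")
        groups = pd.Series(top2, index=var.dropna().index)
        assert groups[[f"d{i}" for i in range(6)]].nunique() == 1
        assert groups[[f"r{i}" for i in range(6)]].nunique() == 1
        assert groups["d0"] != groups["r0"]


class TestPeakGeneTally:
    def _models(self):
        return pd.DataFrame(
            [
                ("geneA", "chr1", 1000, 2000, "+"),
                ("geneB", "chr1", 5000, 6000, "+"),
                ("geneC", "chr2", 100, 500, "-"),
            ],
            columns=["gene", "contig", "start", "end", "strand"],
        )

    def test_nearest_gene_wins(self):
        peaks = pd.DataFrame(
            [("chr1", 2050, 2150)], columns=["contig", "start", "end"]
        )  # 50 from geneA, 2850 from geneB
        out = peak_gene_tally(peaks, self._models(), [])
        assert list(out.index) == ["geneA"]

    def test_overlap_is_distance_zero(self):
        peaks = pd.DataFrame(
            [("chr1", 1900, 2100)], columns=["contig", "start", "end"]
        )
        out = peak_gene_tally(peaks, self._models(), [])
        assert list(out.index) == ["geneA"]
        assert out.loc["geneA", "peak_length"] == 200

    def test_equidistant_tie_lexicographic(self):
        models = pd.DataFrame(
            [
                ("zzz", "chr1", 0, 100, "+"),
                ("aaa", "chr1", 300, 400, "+"),
            ],
            columns=["gene", "contig", "start", "end", "strand"],
        )
        peaks = pd.DataFrame(
            [("chr1", 150, 250)], columns=["contig", "start", "end"]
        )  # 50 from both
        out = peak_gene_tally(peaks, models, [])
        assert list(out.index) == ["aaa"]

    def test_manual_fixture_totals(self):
        models = self._models()
        peaks = pd.DataFrame(
            [
                ("chr1", 900, 1100),   # overlaps geneA, len 200
                ("chr1", 2100, 2200),  # nearer geneA, len 100
                ("chr1", 4800, 4900),  # nearer geneB, len 100
                ("chr1", 6100, 6400),  # nearer geneB, len 300
                ("chr2", 50, 150),     # overlaps geneC, len 100
                ("chr2", 700, 900),    # nearer geneC, len 200
            ],
            columns=["contig", "start", "end"],
        )
        hits = [
            MotifHit("chr1:900-1100", 10, "+", 5.0, 0.9, "E", 6),
            MotifHit("chr1:900-1100", 50, "+", 5.0, 0.9, "E", 6),
            MotifHit("chr1:4800-4900", 10, "+", 5.0, 0.9, "E", 6),
            MotifHit("chr1:4800-4900", 11, "+", 6.0, 0.95, "E", 6),  # deduped
        ]
        out = peak_gene_tally(peaks, models, hits)
        assert out.loc["geneA", "peak_length"] == 300
        assert out.loc["geneA", "n_sites"] == 2
        assert out.loc["geneB", "peak_length"] == 400
        assert out.loc["geneB", "n_sites"] == 1
        assert out.loc["geneC", "peak_length"] == 300
        assert out.loc["geneC", "n_sites"] == 0
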