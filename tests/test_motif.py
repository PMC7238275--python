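import itertools
import math

import numpy as np
import pandas as pd
import pytest

from podmat.datamodel_io import GeneModel, ValidationError
from podmat.motif import (
    PWM,
    ScoreDistribution,
    extract_promoters,
    filter_evidence,
    log_odds,
    pwm_pvalue_dp,
    read_meme,
    reverse_complement,
    scan_sites,
    write_meme,
)


def uniform_pwm(width=2, motif_id="M1", pseudo=0.001):
    return PWM(motif_id, np.full((width, 4), 0.25), pseudo=pseudo)


def random_pwm(rng, width, motif_id="M1"):
    probs = rng.dirichlet(np.full(4, 0.7), size=width)
    return PWM(motif_id, probs)


def enumerate_exact(pwm):
    """All word scores (summed in scan order) and their background probs."""
    lom = pwm.log_odds_matrix
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        s = 0.0
        pr = 1.0
        for i, c in enumerate(word):
            s += lom[i, c]
            pr *= pwm.background[c]
        scores.append(s)
        probs.append(pr)
    order = np.argsort(scores)[::-1]
    return np.array(scores)[order], np.cumsum(np.array(probs)[order])


def exact_tail(scores_desc, cum_probs, threshold):
    idx = np.searchsorted(-scores_desc, -(threshold - 1e-12), side="right")
    return cum_probs[idx - 1] if idx > 0 else 0.0


class TestPWM:
    def test_row_sum_invariant(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            PWM("M", np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            PWM("M", np.array([[1.2, -0.2, 0.0, 0.0]]))

    def test_consensus(self):
        pwm = PWM("M", np.array([[0.7, 0.1, 0.1, 0.1],
                                 [0.1, 0.1, 0.1, 0.7]]))
        assert pwm.consensus == "AT"

    def test_reverse_complement_probs(self):
        pwm = PWM("M", np.array([[0.7, 0.1, 0.1, 0.1],
                                 [0.1, 0.6, 0.2, 0.1]]))
        rc = pwm.reverse_complement()
        assert rc.probs[0, 2] == pytest.approx(0.6)  # C at pos1 -> G at pos0
        assert rc.probs[1, 3] == pytest.approx(0.7)  # A at pos0 -> T at pos1


class TestLogOdds:
    def test_background_rows_score_zero(self):
        pwm = uniform_pwm(width=3)
        for word in ("ACG", "TTT", "GAT"):
            assert log_odds(pwm, word) == pytest.approx(0.0, abs=1e-12)

    def test_pseudo_probability_rule(self):
        pwm = PWM("M", np.array([[1.0, 0.0, 0.0, 0.0]]), pseudo=0.001)
        assert log_odds(pwm, "A") == pytest.approx(math.log2(0.997 / 0.25))
        assert log_odds(pwm, "C") == pytest.approx(math.log2(0.001 / 0.25))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            log_odds(uniform_pwm(2), "ACG")

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 5)
        for word in ("ACGTA", "TTGCA", "GGGGG"):
            assert log_odds(pwm.reverse_complement(), word) == pytest.approx(
                log_odds(pwm, reverse_complement(word)))


class TestPvalueDP:
    def test_minimal_score_p_one(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 4)
        minimal = float(pwm.log_odds_matrix.min(axis=1).sum())
        assert pwm_pvalue_dp(pwm, minimal) == 1.0

    def test_w1_best_letter_quarter(self):
        pwm = PWM("M", np.array([[0.7, 0.1, 0.1, 0.1]]))
        best = log_odds(pwm, "A")
        assert pwm_pvalue_dp(pwm, best) == pytest.approx(0.25)

    def test_w2_matches_enumeration(self):
        rng = np.random.default_rng(6)
        pwm = random_pwm(rng, 2)
        dist = ScoreDistribution(pwm)
        scores_desc, cum = enumerate_exact(pwm)
        slack = pwm.width * dist.bin_width
        for s in scores_desc:
            p_dp = dist.pvalue(s)
            assert p_dp >= exact_tail(scores_desc, cum, s) - 1e-12
            assert p_dp <= exact_tail(scores_desc, cum, s - slack) + 1e-12

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_dp_within_one_bin_of_enumeration(self, width):
        rng = np.random.default_rng(width)
        for _ in range(5):
            pwm = random_pwm(rng, width)
            dist = ScoreDistribution(pwm)
            scores_desc, cum = enumerate_exact(pwm)
            slack = width * dist.bin_width
            sample = rng.choice(scores_desc.size, size=40, replace=False)
            for s in scores_desc[sample]:
                p_dp = dist.pvalue(s)
                assert p_dp >= exact_tail(scores_desc, cum, s) - 1e-12
                assert p_dp <= exact_tail(scores_desc, cum, s - slack) + 1e-12

    def test_degenerate_pwm_rejected(self):
        pwm = PWM("M", np.array([[1.0, 0.0, 0.0, 0.0]]), pseudo=0.0)
        with pytest.raises(ValidationError, match="degenerate"):
            pwm_pvalue_dp(pwm, 0.0)

    def test_bins_floor(self):
        with pytest.raises(ValidationError, match="bins"):
            pwm_pvalue_dp(uniform_pwm(), 0.0, bins=10)


class TestExtractPromoters:
    GENOME = {"c1": "".join(
        np.random.default_rng(9).choice(list("ACGT"), size=2000))}

    def test_plus_strand_window(self):
        model = GeneModel("g", "c1", "+", 1000, 100)
        out = extract_promoters([model], self.GENOME)
        assert out["g"] == self.GENOME["c1"][500:1100]
        assert len(out["g"]) == 600

    def test_minus_strand_window(self):
        model = GeneModel("g", "c1", "-", 1000, 100)
        out = extract_promoters([model], self.GENOME)
        assert out["g"] == reverse_complement(self.GENOME["c1"][901:1501])

    def test_clipping_at_contig_start(self):
        model = GeneModel("g", "c1", "+", 100, 50)
        out = extract_promoters([model], self.GENOME)
        assert out["g"] == self.GENOME["c1"][0:200]
        assert len(out["g"]) == 200

    def test_missing_contig_errors(self):
        with pytest.raises(ValidationError, match="contig"):
            extract_promoters([GeneModel("g", "nope", "+", 500, 10)], self.GENOME)

    def test_matches_generator_promoters(self, noise_free_dataset):
        ds = noise_free_dataset
        out = extract_promoters(ds.models, ds.genome)
        assert out == ds.promoters


def brute_force_sites(pwm, promoters, p_threshold, bins=1000):
    dist = ScoreDistribution(pwm, bins=bins)
    rows = []
    for gene, seq in promoters.items():
        for offset in range(len(seq) - pwm.width + 1):
            window = seq[offset:offset + pwm.width]
            if any(c not in "ACGT" for c in window):
                continue
            for strand in "+-":
                word = window if strand == "+" else reverse_complement(window)
                score = log_odds(pwm, word)
                p = dist.pvalue(score)
                if p <= p_threshold:
                    rows.append((pwm.motif_id, gene, offset, strand, score, p))
    return rows


class TestScanSites:
    def test_planted_consensus_found(self, noise_free_dataset):
        ds = noise_free_dataset
        sites = scan_sites(ds.pwms, ds.promoters, p_threshold=1e-5)
        found = set(zip(sites["motif_id"], sites["gene_id"],
                        sites["offset"], sites["strand"]))
        for motif_id, gene, offset in ds.manifest.planted_motif_sites:
            assert (motif_id, gene, offset, "+") in found

    def test_all_n_promoter_no_sites(self):
        pwm = PWM("M", np.array([[0.9, 0.05, 0.03, 0.02]] * 4))
        sites = scan_sites([pwm], {"g": "N" * 50}, p_threshold=1.0)
        assert sites.empty

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        promoters = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=300))
            for i in range(5)
        }
        pwms = [random_pwm(rng, w, motif_id=f"M{w}") for w in (4, 6, 8)]
        got = scan_sites(pwms, promoters, p_threshold=1e-2)
        got_set = {(r.motif_id, r.gene_id, r.offset, r.strand)
                   for r in got.itertuples()}
        expected = set()
        for pwm in pwms:
            for row in brute_force_sites(pwm, promoters, 1e-2):
                expected.add(row[:4])
        assert got_set == expected

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        promoters = {"g": "".join(rng.choice(list("ACGT"), size=400))}
        pwm = random_pwm(rng, 5)
        loose = scan_sites([pwm], promoters, p_threshold=1e-2)
        tight = scan_sites([pwm], promoters, p_threshold=1e-3)
        loose_keys = set(zip(loose["offset"], loose["strand"]))
        tight_keys = set(zip(tight["offset"], tight["strand"]))
        assert tight_keys <= loose_keys

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pwm = random_pwm(rng, 6)
        fwd = scan_sites([pwm], {"g": seq}, p_threshold=5e-2)
        rev = scan_sites([pwm.reverse_complement()],
                         {"g": reverse_complement(seq)}, p_threshold=5e-2)
        # strand is preserved, offsets mirror: the rc PWM on the rc sequence
        # sees the same words at position L - W - o
        mirror = {(s, len(seq) - pwm.width - o)
                  for o, s in zip(rev["offset"], rev["strand"])}
        assert {(s, o) for o, s in zip(fwd["offset"], fwd["strand"])} == mirror


class TestFilterEvidence:
    def _sites(self):
        return pd.DataFrame(
            [("M1", "g1", 10, "+", 5.0, 1e-6, "motif"),
             ("M1", "g2", 10, "+", 5.0, 1e-6, "motif")],
            columns=["motif_id", "gene_id", "offset", "strand", "score",
                     "p_value", "evidence"])

    def test_motif_mode_identity(self):
        sites = self._sites()
        out = filter_evidence(sites, mode="motif")
        pd.testing.assert_frame_equal(out, sites)

    def test_motif_ce_strict_majority_overlap(self):
        sites = self._sites()  # 10-bp sites at [10, 20)
        conserved = pd.DataFrame(
            [("g1", 14, 40),   # overlap 6 bp -> kept (60% > 50%)
             ("g2", 15, 40)],  # overlap 5 bp -> dropped (exactly 50%)
            columns=["gene_id", "start", "end"])
        out = filter_evidence(sites, conserved=conserved, mode="motif_CE",
                              widths={"M1": 10})
        assert list(out["gene_id"]) == ["g1"]
        assert (out["evidence"] == "motif_CE").all()

    def test_motif_ce_requires_track(self):
        with pytest.raises(ValidationError, match="conserved"):
            filter_evidence(self._sites(), mode="motif_CE", widths={"M1": 10})

    def test_funtfbs_labels(self):
        out = filter_evidence(self._sites(),
                              functional={("M1", "g2", 10, "+")},
                              mode="FunTFBS")
        assert list(out["gene_id"]) == ["g2"]
        assert (out["evidence"] == "FunTFBS").all()

    def test_unknown_mode(self):
        with pytest.raises(ValidationError, match="unknown evidence mode"):
            filter_evidence(self._sites(), mode="bogus")


class TestMemeFormat:
    def test_round_trip(self, tmp_path, noise_free_dataset):
        path = tmp_path / "motifs.meme"
        write_meme(noise_free_dataset.pwms, path)
        back = read_meme(path)
        assert [p.motif_id for p in back] == \
               [p.motif_id for p in noise_free_dataset.pwms]
        for a, b in zip(back, noise_free_dataset.pwms):
            assert np.allclose(a.probs, b.probs, atol=5e-7)
            assert np.allclose(a.background, b.background)

    def test_background_line_parsed(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
            "MOTIF MX\nletter-probability matrix: alength= 4 w= 2\n"
            " 0.25 0.25 0.25 0.25\n 0.1 0.4 0.4 0.1\n")
        (pwm,) = read_meme(path)
        assert pwm.width == 2
        assert pwm.background[0] == pytest.approx(0.3)
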