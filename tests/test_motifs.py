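import numpy as np
import pytest
from scipy.stats import pearsonr

from ocrdenovo.data import one_hot_encode
from ocrdenovo.motifs import (
    PFM,
    PWM,
    build_pfm,
    consensus,
    harvest_activations,
    pfm_to_pwm,
    pwm_similarity,
    read_meme,
    write_logo_heights,
    write_meme,
)
from ocrdenovo.nn import ModelSpec, build_model


def _random_pwm(width, seed, name="m"):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4) * 0.7, size=width).T
    return PWM(probs=probs, name=name)


class TestPFM:
    def test_counting(self):
        pfm = build_pfm(["ACG", "ACG"])
        assert pfm.n_sites == 2
        assert np.array_equal(pfm.counts, [[2, 0, 0], [0, 2, 0], [0, 0, 2], [0, 0, 0]])

    def test_mixed_column(self):
        pfm = build_pfm(["AT", "TA"])
        assert np.array_equal(pfm.counts, [[1, 1], [0, 0], [0, 0], [1, 1]])

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 7)) for _ in range(23)]
        pfm = build_pfm(seqs)
        assert np.all(pfm.counts.sum(axis=0) == 23)

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            build_pfm(["ACG", "AC"])


class TestPWM:
    def test_stochastic_columns_and_ic_range(self):
        pwm = pfm_to_pwm(build_pfm(["ACGT", "ACGA", "TCGA"]))
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)
        assert np.all((pwm.ic >= 0) & (pwm.ic <= 2))
        assert np.allclose(pwm.logo_heights, pwm.probs * pwm.ic)

    def test_hand_entropy_value(self):
        pfm = PFM(np.array([[7], [1], [1], [1]]), n_sites=10)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        assert pwm.ic[0] == pytest.approx(0.6432, abs=5e-5)

    def test_consensus(self):
        pwm = pfm_to_pwm(build_pfm(["TATAAT"] * 5))
        assert consensus(pwm) == "TATAAT"


class TestSimilarity:
    def test_self_similarity(self):
        a = _random_pwm(9, 1)
        score, offset, orient = pwm_similarity(a, a)
        assert score == pytest.approx(1.0)
        assert (offset, orient) == (0, "+")

    def test_reverse_complement_detected(self):
        a = _random_pwm(9, 2)
        score, offset, orient = pwm_similarity(a, a.reverse_complement())
        assert score == pytest.approx(1.0)
        assert orient == "-"

    def test_matches_brute_force_enumeration(self):
        for seed in range(8):
            a = _random_pwm(10, seed)
            b = _random_pwm(7, 100 + seed)
            got, _, _ = pwm_similarity(a, b)
            best = -2
            for bb in (b.probs, b.probs[::-1, ::-1]):
                wb = bb.shape[1]
                for off in range(-wb + 4, a.width - 4 + 1):
                    lo, hi = max(0, off), min(a.width, off + wb)
                    if hi - lo < 4:
                        continue
                    r = pearsonr(
                        a.probs[:, lo:hi].ravel(),
                        bb[:, lo - off : hi - off].ravel(),
                    ).statistic
                    best = max(best, r)
            assert got == pytest.approx(best, abs=1e-12)

    def test_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            pwm_similarity(_random_pwm(3, 0), _random_pwm(9, 1))


class TestHarvest:
    def _planted_model_and_input(self):
        spec = ModelSpec(conv1_filters=2, conv1_width=6, conv2_filters=2,
                         conv2_width=3, fc_units=4, input_length=24, seed=0)
        model = build_model(spec)
        model.params["W1"][0] = one_hot_encode("TATAAT").ravel()
        model.params["W1"][1] = 0.0  # dead filter
        model.params["b1"][:] = 0.0
        model.trained = True
        seq = "GCGCGCTATAATGCGCGCGCGCGC"
        return model, np.stack([one_hot_encode(seq)]), seq

    def test_planted_filter_recovers_its_site(self):
        model, X, seq = self._planted_model_and_input()
        subseqs, inactive = harvest_activations(model, X, threshold_frac=0.5, min_hits=1)
        assert "TATAAT" in subseqs[0]

    def test_threshold_one_keeps_only_argmax(self):
        model, X, seq = self._planted_model_and_input()
        subseqs, _ = harvest_activations(model, X, threshold_frac=1.0, min_hits=0)
        # strict inequality with the max itself excluded -> nothing survives
        assert subseqs[0] == []

    def test_dead_filter_flagged_inactive(self):
        model, X, _ = self._planted_model_and_input()
        _, inactive = harvest_activations(model, X, min_hits=1)
        assert 1 in inactive

    def test_untrained_model_rejected(self):
        model, X, _ = self._planted_model_and_input()
        model.trained = False
        with pytest.raises(ValueError):
            harvest_activations(model, X)


class TestMemeFormat:
    def test_round_trip(self, tmp_path):
        pwms = [_random_pwm(8, 3, "alpha"), _random_pwm(12, 4, "beta")]
        path = tmp_path / "m.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["alpha", "beta"]
        for p, q in zip(pwms, back):
            assert np.allclose(p.probs, q.probs, atol=1e-6)

    def test_empty_list_gives_valid_header(self, tmp_path):
        path = tmp_path / "empty.meme"
        write_meme([], path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert read_meme(path) == []

    def test_hand_written_two_column_motif(self, tmp_path):
        path = tmp_path / "hand.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF tiny\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 5 E= 0\n"
            "1.0 0.0 0.0 0.0\n0.0 0.0 0.0 1.0\n"
        )
        (pwm,) = read_meme(path)
        assert consensus(pwm) == "AT"
        assert pwm.n_sites == 5

    def test_non_stochastic_rejected(self, tmp_path):
        bad = PWM(np.full((4, 3), 0.25))
        bad.probs[0, 0] = 0.5  # corrupt after validation
        with pytest.raises(ValueError):
            write_meme([bad], tmp_path / "bad.meme")

    def test_logo_heights_file(self, tmp_path):
        pwm = _random_pwm(5, 9)
        write_logo_heights(pwm, tmp_path / "logo.tsv")
        lines = (tmp_path / "logo.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["position", "A", "C", "G", "T", "ic_bits"]
        assert len(lines) == 6
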