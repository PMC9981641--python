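import numpy as np
import pytest

from emabayes import (
    EffectSpec,
    EmaDataset,
    EmaFrame,
    EmaRecord,
    StackedLikelihood,
    param_dimension,
    total_log_likelihood,
)
from emabayes.likelihood import IndividualParams
from emabayes.response import raw_to_interior, response_prob
from emabayes.situations import situation_probs


class TestParamDimension:
    def test_hearing_study_configuration_gives_75(self):
        frame = EmaFrame(
            phases=["before", "after"],
            situation_dims={"coss": [f"C{j}" for j in range(1, 8)]},
            attributes={
                "loudness": [str(j) for j in range(7)],
                "involvement": [str(j) for j in range(5)],
                "disability": [str(j) for j in range(7)],
            },
        )
        D, parts = param_dimension(frame)
        assert (parts["situation"], parts["effects"], parts["thresholds"]) == (14, 42, 19)
        assert D == 75

    def test_degenerate_minimum(self):
        frame = EmaFrame(phases=["p"], situation_dims={"d": ["c"]})
        D, parts = param_dimension(frame)
        assert D == 1
        assert parts == {"situation": 1, "effects": 0, "thresholds": 0}

    def test_two_by_three_dims_no_attributes(self):
        frame = EmaFrame(
            phases=["p"],
            situation_dims={"location": ["in", "out"], "noise": ["q", "m", "l"]},
        )
        D, _ = param_dimension(frame)
        assert D == 6


def _single_participant_dataset(frame, records):
    return EmaDataset(frame, records)


@pytest.fixture(scope="module")
def small_frame():
    return EmaFrame(
        phases=["p1", "p2"],
        situation_dims={"d": ["a", "b"]},
        attributes={"q": ["1", "2", "3"]},
    )


class TestTotalLogLikelihood:
    def test_zero_record_participant_contributes_zero(self, small_frame):
        ds = EmaDataset(
            small_frame,
            [EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {"q": 1})],
            participant_groups={"empty": "group"},
        )
        lik = StackedLikelihood(ds)
        xi = np.zeros(lik.dim)
        n = lik.participants.index("empty")
        ll, g = lik._eval_one(n, xi)
        # only the (vanishing) situation term with zero counts remains
        assert ll == pytest.approx(0.0)
        assert np.allclose(g, 0.0)

    def test_situation_only_records_reduce_to_situation_term(self, small_frame, rng):
        recs = [
            EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {}),
            EmaRecord.validate(small_frame, "x", "group", "p1", ("b",), {}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("b",), {}),
        ]
        ds = _single_participant_dataset(small_frame, recs)
        xi = rng.normal(size=param_dimension(small_frame)[0])
        ll, _ = total_log_likelihood(xi, ds, "x")
        blocks = StackedLikelihood(ds).blocks
        u = situation_probs(xi[blocks.situation_slice].reshape(2, 2))
        expected = np.log(u[0, 0]) + np.log(u[0, 1]) + np.log(u[1, 1])
        assert ll == pytest.approx(expected)

    def test_matches_hand_assembled_brute_force(self, small_frame, rng):
        recs = [
            EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {"q": 1}),
            EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {"q": 3}),
            EmaRecord.validate(small_frame, "x", "group", "p1", ("b",), {}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("b",), {"q": 2}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("b",), {"q": 2}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("a",), {"q": 1}),
        ]
        ds = _single_participant_dataset(small_frame, recs)
        lik = StackedLikelihood(ds)
        b = lik.blocks
        xi = rng.normal(size=lik.dim)
        ll, _ = total_log_likelihood(xi, ds, "x")

        # independent assembly from the elementary pieces
        u = situation_probs(xi[b.situation_slice].reshape(2, 2))
        theta = lik.design.matrix @ xi[b.effect_slice("q")]
        interior = raw_to_interior(xi[b.threshold_slice("q")], "median-zero")
        cell = {("p1", "a"): 0, ("p1", "b"): 1, ("p2", "a"): 2, ("p2", "b"): 3}
        expected = 0.0
        for r in recs:
            t = small_frame.phase_index(r.phase)
            k = small_frame.cell_index(r.situation)
            expected += np.log(u[t, k])
            v = r.ratings["q"]
            if v is not None:
                c = cell[(r.phase, r.situation[0])]
                expected += np.log(response_prob(theta[c], interior)[v - 1])
        assert ll == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self, small_frame, rng):
        recs = [
            EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {"q": 2}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("b",), {"q": 3}),
        ]
        ds = _single_participant_dataset(small_frame, recs)
        xi = rng.normal(size=param_dimension(small_frame)[0])
        ll, g = total_log_likelihood(xi, ds, "x")
        eps = 1e-6
        for d in range(len(xi)):
            xp, xm = xi.copy(), xi.copy()
            xp[d] += eps
            xm[d] -= eps
            fd = (
                total_log_likelihood(xp, ds, "x")[0]
                - total_log_likelihood(xm, ds, "x")[0]
            ) / (2 * eps)
            assert g[d] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_zero_mean_attribute_mode_gradient(self, small_frame, rng):
        recs = [
            EmaRecord.validate(small_frame, "x", "group", "p1", ("a",), {"q": 2}),
            EmaRecord.validate(small_frame, "x", "group", "p2", ("b",), {"q": 1}),
        ]
        ds = _single_participant_dataset(small_frame, recs)
        xi = rng.normal(size=param_dimension(small_frame)[0])
        ll, g = total_log_likelihood(xi, ds, "x", mode="zero-mean-attribute")
        eps = 1e-6
        for d in range(len(xi)):
            xp, xm = xi.copy(), xi.copy()
            xp[d] += eps
            xm[d] -= eps
            fd = (
                total_log_likelihood(xp, ds, "x", mode="zero-mean-attribute")[0]
                - total_log_likelihood(xm, ds, "x", mode="zero-mean-attribute")[0]
            ) / (2 * eps)
            assert g[d] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestIndividualParams:
    def test_block_views_cover_vector(self, toy_frame):
        spec = EffectSpec.saturated(toy_frame)
        from emabayes.likelihood import ParamBlocks
        from emabayes.design import design_matrix

        blocks = ParamBlocks(
            frame=toy_frame, spec=spec,
            n_effect_params=design_matrix(spec, toy_frame).n_params,
        )
        xi = np.arange(blocks.dim, dtype=float)
        p = IndividualParams(xi, blocks)
        seen = np.concatenate(
            [p.situation_logits.ravel()]
            + [p.effects(a) for a in toy_frame.attributes]
            + [p.raw_thresholds(a) for a in toy_frame.attributes]
        )
        assert np.array_equal(np.sort(seen), xi)
        assert sum(blocks.breakdown().values()) == blocks.dim

    def test_wrong_length_rejected(self, toy_frame):
        from emabayes.likelihood import ParamBlocks
        from emabayes.design import design_matrix

        spec = EffectSpec.saturated(toy_frame)
        blocks = ParamBlocks(
            frame=toy_frame, spec=spec,
            n_effect_params=design_matrix(spec, toy_frame).n_params,
        )
        with pytest.raises(ValueError):
            IndividualParams(np.zeros(blocks.dim + 1), blocks)
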