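import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoptox.dge import DEGTable, RegulonSets, call_regulons, signed_fold_change
from stoptox.indices import (
    antagonism_fractions,
    baseline_stratify,
    category_indices,
    compute_di,
    compute_dp,
    compute_overlap,
    concentration_profile,
    index_result,
    overlap_significance,
)
from stoptox.io_model import (
    ExpressionMatrix,
    GeneSetCollection,
    PROBE,
    SampleDesign,
    ValidationError,
)
from stoptox.synthetic import PlantedCompound, SynthConfig, generate_dataset
from stoptox.dge import differential_expression


def fisher_tail_oracle(O, T, D, N):
    """Independent hypergeometric upper tail by direct combinatorial sum."""
    total = 0.0
    denom = math.comb(N, T)
    for x in range(O, min(D, T) + 1):
        total += math.comb(D, x) * math.comb(N - D, T - x) / denom
    return total


class TestOverlap:
    def test_disjoint_sets_give_zero(self):
        d = RegulonSets(up={"a"}, down={"b"}, label="D")
        t = RegulonSets(up={"x"}, down={"y"}, label="T")
        O, quads = compute_overlap(d, t)
        assert O == 0 and all(v == 0 for v in quads.values())

    def test_directional_quadrant_example(self):
        d = RegulonSets(up={"a", "b"}, down=set(), label="D")
        t = RegulonSets(up=set(), down={"b", "c"}, label="T")
        O, quads = compute_overlap(d, t)
        assert O == 1
        assert quads == {"Tup_Dup": 0, "Tup_Ddown": 0, "Tdown_Dup": 1, "Tdown_Ddown": 0}

    def test_quadrants_match_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        ids = [f"g{i}" for i in range(1000)]
        for _ in range(10):
            d_ids = rng.choice(ids, size=100, replace=False)
            t_ids = rng.choice(ids, size=80, replace=False)
            d = RegulonSets(up=set(d_ids[:60]), down=set(d_ids[60:]), label="D")
            t = RegulonSets(up=set(t_ids[:30]), down=set(t_ids[30:]), label="T")
            O, quads = compute_overlap(d, t)
            assert O == len((d.up | d.down) & (t.up | t.down))
            assert quads["Tup_Ddown"] == len(t.up & d.down)
            assert quads["Tdown_Dup"] == len(t.down & d.up)
            assert sum(quads.values()) == O  # direction sets are disjoint

    def test_namespace_mismatch_is_error(self):
        d = RegulonSets(up={"a"}, down=set(), label="D", namespace="probe")
        t = RegulonSets(up={"a"}, down=set(), label="T", namespace="gene")
        with pytest.raises(ValidationError, match="namespace"):
            compute_overlap(d, t)


class TestDpDi:
    def test_dp_extremes_and_arithmetic(self):
        assert compute_dp(0, 10) == 0.0
        assert compute_dp(10, 10) == 1.0
        assert compute_dp(500, 4000) == 0.125

    def test_dp_requires_developmental_signal(self):
        with pytest.raises(ValidationError):
            compute_dp(0, 0)

    def test_di_random_expectation_is_one(self):
        # O/T exactly equals D/N -> Di = 1.0
        assert compute_di(O=10, T=100, D=1000, N=10000) == pytest.approx(1.0)

    def test_di_direct_arithmetic(self):
        assert compute_di(O=50, T=100, D=1000, N=54675) == pytest.approx(27.3375)

    def test_di_zero_overlap(self):
        assert compute_di(O=0, T=100, D=1000, N=54675) == 0.0

    def test_di_undefined_for_negative_test(self):
        assert math.isnan(compute_di(O=0, T=0, D=1000, N=54675))

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_di_identity_holds_algebraically(self, data):
        N = data.draw(st.integers(10, 100000))
        D = data.draw(st.integers(1, N))
        T = data.draw(st.integers(1, N))
        O = data.draw(st.integers(0, min(D, T)))
        di = compute_di(O, T, D, N)
        assert di == pytest.approx((O * N) / (T * D), rel=1e-12)
        # consistency with Dp: Di = Dp * N / T
        assert di == pytest.approx(compute_dp(O, D) * N / T, rel=1e-12)


class TestFisher:
    def test_hand_enumerated_example(self):
        # N=20, D=5, T=4, O=4: only C(5,4)*C(15,0)=5 of C(20,4)=4845 draws
        assert overlap_significance(4, 4, 5, 20) == pytest.approx(
            5 / 4845, rel=1e-12
        )

    def test_zero_overlap_gives_p_one(self):
        assert overlap_significance(0, 10, 10, 100) == pytest.approx(1.0)

    def test_single_overlap_closed_form(self):
        expected = 1 - math.comb(90, 10) / math.comb(100, 10)
        assert overlap_significance(1, 10, 10, 100) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_enumeration_oracle_on_random_configs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            N = int(rng.integers(10, 501))
            D = int(rng.integers(1, N + 1))
            T = int(rng.integers(1, N + 1))
            O = int(rng.integers(0, min(D, T) + 1))
            got = overlap_significance(O, T, D, N)
            assert got == pytest.approx(fisher_tail_oracle(O, T, D, N), abs=1e-12)

    def test_overlap_larger_than_sets_is_error(self):
        with pytest.raises(ValidationError):
            overlap_significance(11, 10, 100, 1000)


class TestAntagonism:
    def test_empty_t_gives_zero_fractions(self):
        d = RegulonSets(up={"a"}, down={"b"}, label="D")
        t = RegulonSets(up=set(), down=set(), label="T")
        fr = antagonism_fractions(d, t)
        assert all(v["fraction"] == 0.0 for v in fr.values())

    def test_perfect_antagonism(self):
        d = RegulonSets(up={"a", "b"}, down=set(), label="D")
        t = RegulonSets(up=set(), down={"a", "b"}, label="T")
        fr = antagonism_fractions(d, t)
        assert fr["Tdown_Dup"]["fraction"] == 1.0

    def test_empty_d_direction_reported_as_nan(self):
        d = RegulonSets(up={"a"}, down=set(), label="D")
        t = RegulonSets(up={"a"}, down=set(), label="T")
        fr = antagonism_fractions(d, t)
        assert math.isnan(fr["Tup_Ddown"]["fraction"])

    def test_planted_antagonism_fraction_recovered(self):
        config = SynthConfig(
            n_probes=4000,
            d_up=200,
            d_down=200,
            compounds=[
                PlantedCompound(
                    t_up=50, t_down=50, overlap=100, antagonism_fraction=0.7
                )
            ],
            log2fc_range=(1.5, 3.3),
            seed=21,
        )
        matrix, design, _, truth = generate_dataset(config)
        deg_d = differential_expression(
            matrix,
            design.samples_with_role("day0_control"),
            design.samples_with_role("diff_control"),
        )
        deg_t = differential_expression(
            matrix,
            design.samples_with_role("diff_control"),
            design.samples_for_compound("toxA"),
        )
        d = call_regulons(deg_d, "D")
        t = call_regulons(deg_t, "T")
        res = index_result(d, t, matrix.n_probes)
        assert res.antagonistic_fraction == pytest.approx(0.7, abs=0.05)


class TestCategoryIndices:
    def _regs(self):
        d = RegulonSets(up={f"u{i}" for i in range(20)},
                        down={f"d{i}" for i in range(10)}, label="D")
        t = RegulonSets(up={f"u{i}" for i in range(5)} | {"x1", "x2"},
                        down={f"d{i}" for i in range(3)}, label="T")
        return d, t

    def test_full_d_category_reproduces_global_indices(self):
        d, t = self._regs()
        cats = GeneSetCollection(
            {"all_d": ("", frozenset(d.all))}, namespace=PROBE
        )
        # regulons default to probe namespace
        res = category_indices(d, t, cats, N=1000)["all_d"]
        ref = index_result(d, t, N=1000)
        assert (res.D, res.O, res.Dp) == (ref.D, ref.O, ref.Dp)
        assert res.Di == pytest.approx(ref.Di)

    def test_disjoint_category_is_skipped(self):
        d, t = self._regs()
        cats = GeneSetCollection(
            {"unrelated": ("", frozenset({"z1", "z2"}))}, namespace=PROBE
        )
        assert category_indices(d, t, cats, N=1000) == {}

    def test_per_category_dp_matches_restriction_oracle(self):
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(500)]
        d = RegulonSets(up=set(ids[:80]), down=set(ids[80:120]), label="D")
        t = RegulonSets(up=set(rng.choice(ids, 60, replace=False)), down=set(),
                        label="T")
        cats = GeneSetCollection(
            {
                f"c{k}": ("", frozenset(rng.choice(ids, 100, replace=False)))
                for k in range(3)
            },
            namespace=PROBE,
        )
        results = category_indices(d, t, cats, N=500)
        for name, res in results.items():
            members = cats.members(name)
            d_c = d.all & members
            o_c = d.all & t.all & members
            assert res.D == len(d_c)
            assert res.O == len(o_c)
            assert res.Dp == pytest.approx(len(o_c) / len(d_c))

    def test_empty_collection_is_error(self):
        d, t = self._regs()
        with pytest.raises(ValidationError):
            category_indices(d, t, GeneSetCollection({}, namespace=PROBE), N=100)


class TestBaselineStratify:
    def _setup(self, day0_mean, end_mean):
        values = np.array([[day0_mean] * 2 + [end_mean] * 2])
        m = ExpressionMatrix(["p1"], ["a1", "a2", "c1", "c2"], values)
        design = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": ["a1", "a2", "c1", "c2"],
                    "role": ["day0_control"] * 2 + ["diff_control"] * 2,
                    "compound": None,
                    "compound_class": None,
                    "concentration": None,
                    "conc_unit": None,
                    "system": "UKN1",
                    "batch": "B1",
                    "replicate": [1, 2, 1, 2],
                }
            )
        )
        regs = RegulonSets(up={"p1"}, down=set(), label="D")
        return baseline_stratify(regs, m, design)

    def test_high_when_day0_above_threshold(self):
        assert self._setup(6.5, 3.0).loc["p1", "high_baseline"]

    def test_low_when_both_below(self):
        assert not self._setup(5.9, 5.9).loc["p1", "high_baseline"]

    def test_exactly_six_is_low_strict_inequality(self):
        assert not self._setup(6.0, 6.0).loc["p1", "high_baseline"]

    def test_missing_controls_is_error(self):
        m = ExpressionMatrix(["p1"], ["s1", "s2"], [[1.0, 2.0]])
        design = SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "role": ["treated", "treated"],
                    "compound": "x",
                    "compound_class": "HDACi",
                    "concentration": 1.0,
                    "conc_unit": "uM",
                    "system": "UKN1",
                    "batch": "B1",
                    "replicate": [1, 2],
                }
            )
        )
        regs = RegulonSets(up={"p1"}, down=set(), label="D")
        with pytest.raises(ValidationError):
            baseline_stratify(regs, m, design)


def _deg_from_sets(up, down, universe):
    rows = []
    for p in universe:
        if p in up:
            l2, sig = 2.0, True
        elif p in down:
            l2, sig = -2.0, True
        else:
            l2, sig = 0.0, False
        rows.append((p, l2, sig))
    table = pd.DataFrame(
        {
            "mean_a": 0.0,
            "mean_b": [r[1] for r in rows],
            "log2fc": [r[1] for r in rows],
            "fold_change": signed_fold_change([r[1] for r in rows]),
            "p": 0.001,
            "q": 0.001,
            "significant": [r[2] for r in rows],
        },
        index=[r[0] for r in rows],
    )
    table["direction"] = np.where(
        table["significant"] & (table["log2fc"] > 0),
        "up",
        np.where(table["significant"] & (table["log2fc"] < 0), "down", "none"),
    )
    return DEGTable(table=table, contrast="t", fc_threshold=1.5, q_threshold=0.05)


class TestConcentrationProfile:
    def test_single_concentration_matches_direct_computation(self):
        ids = [f"p{i}" for i in range(100)]
        d = RegulonSets(up=set(ids[:20]), down=set(ids[20:30]), label="D")
        deg = _deg_from_sets(set(ids[:5]), set(ids[95:]), ids)
        profile = concentration_profile([(1.0, deg)], d, N=100)
        t = call_regulons(deg, "T")
        ref = index_result(d, t, N=100)
        row = profile.iloc[0]
        assert (row["T"], row["O"]) == (ref.T, ref.O)
        assert row["Dp"] == pytest.approx(ref.Dp)
        assert row["Di"] == pytest.approx(ref.Di)

    def test_monotone_growing_t_gives_nondecreasing_dp(self):
        ids = [f"p{i}" for i in range(200)]
        d = RegulonSets(up=set(ids[:40]), down=set(), label="D")
        series = []
        for k, conc in enumerate([1.0, 3.0, 10.0, 30.0]):
            n_hit = 5 * (k + 1)  # overlap grows with dose
            deg = _deg_from_sets(set(ids[:n_hit]), set(), ids)
            series.append((conc, deg))
        profile = concentration_profile(series, d, N=200)
        assert (np.diff(profile["Dp"]) >= 0).all()

    def test_cytotoxic_top_dose_depresses_di(self):
        # high dose adds only non-developmental "cell death" genes: Di drops
        ids = [f"p{i}" for i in range(500)]
        d = RegulonSets(up=set(ids[:50]), down=set(), label="D")
        low = _deg_from_sets(set(ids[:20]), set(), ids)
        high = _deg_from_sets(set(ids[:20]) | set(ids[100:400]), set(), ids)
        profile = concentration_profile([(1.0, low), (10.0, high)], d, N=500)
        assert profile["Di"].iloc[1] < profile["Di"].iloc[0]

    def test_duplicate_concentrations_rejected(self):
        ids = ["p1", "p2"]
        d = RegulonSets(up={"p1"}, down=set(), label="D")
        deg = _deg_from_sets({"p1"}, set(), ids)
        with pytest.raises(ValidationError):
            concentration_profile([(1.0, deg), (1.0, deg)], d, N=2)


class TestNullCalibration:
    def test_random_t_sets_give_unit_di_and_superuniform_p(self):
        rng = np.random.default_rng(2024)
        N, D, T = 20_000, 1_000, 100
        ids = np.arange(N)
        d_ids = rng.choice(ids, size=D, replace=False)
        d = RegulonSets(
            up={f"g{i}" for i in d_ids[:500]},
            down={f"g{i}" for i in d_ids[500:]},
            label="D",
        )
        dis, sig = [], 0
        n_draws = 300
        for _ in range(n_draws):
            t_ids = rng.choice(ids, size=T, replace=False)
            t = RegulonSets(up={f"g{i}" for i in t_ids}, down=set(), label="T")
            res = index_result(d, t, N)
            dis.append(res.Di)
            sig += res.fisher_p <= 0.05
        assert np.mean(dis) == pytest.approx(1.0, abs=0.05)
        assert sig / n_draws <= 0.06
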