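"""Generator contracts: determinism, spacing, HWE, noise models, variance shares."""

import datetime as dt

import numpy as np
import pytest

from migrasv.synth import (
    DEFAULT_REPEAT_MIX,
    RouteSpec,
    SizeLaw,
    TraitModel,
    blackcap_profile,
    make_layout,
    rhumb_destination,
    simulate_annotations,
    simulate_caller_callsets,
    simulate_genotypes,
    simulate_group_frequencies,
    simulate_neutral_spectrum,
    simulate_phenotypes,
    simulate_svs,
    simulate_tracks,
)


@pytest.fixture(scope="module")
def layout():
    return make_layout()


class TestSimulateSVs:
    def test_deterministic_given_seed(self, layout):
        a = simulate_svs(layout, 500, seed=3)
        b = simulate_svs(layout, 500, seed=3)
        assert a == b

    def test_pure_type_mix(self, layout):
        loci = simulate_svs(layout, 300, type_mix={"DEL": 1.0}, seed=4)
        assert all(r.svtype == "DEL" for r in loci)

    def test_minimum_start_spacing_two_kb(self, layout):
        loci = simulate_svs(layout, 1000, seed=5)
        by_chrom: dict[str, list[int]] = {}
        for r in loci:
            by_chrom.setdefault(r.chrom, []).append(r.start)
        for starts in by_chrom.values():
            assert np.all(np.diff(sorted(starts)) >= 2000)

    def test_size_law_median_near_configured(self):
        law = SizeLaw()
        lengths = law.sample("DEL", np.random.default_rng(6), 5000)
        assert np.median(lengths) == pytest.approx(250, rel=0.2)

    def test_too_small_layout_is_an_error(self):
        from migrasv.io import GenomeLayout

        with pytest.raises(ValueError):
            simulate_svs(GenomeLayout({"chr1": 10_000}), 100, seed=0)


class TestGroupFrequencies:
    def test_zero_divergence_limit(self):
        anc, freqs = simulate_group_frequencies(200, ["A", "B"], F=0.0, seed=7)
        assert np.allclose(freqs["A"], anc) and np.allclose(freqs["B"], anc)

    def test_selected_shift_clamped(self):
        anc, freqs = simulate_group_frequencies(
            50, ["A"], F=0.02, selected=[(0, "A", 5.0)], seed=8
        )
        assert freqs["A"][0] == 1.0

    def test_balding_nichols_variance_scales_with_f(self):
        anc, freqs = simulate_group_frequencies(20_000, ["A"], F=0.1, seed=9)
        dev = freqs["A"] - anc
        expected_var = np.mean(0.1 * anc * (1 - anc))
        assert dev.var() == pytest.approx(expected_var, rel=0.1)


class TestGenotypes:
    def test_fixed_frequencies(self):
        loci = simulate_svs(make_layout(), 3, seed=10)
        _, freqs = simulate_group_frequencies(3, ["A"], F=0.02, seed=11)
        freqs["A"] = np.array([0.0, 1.0, 0.5])
        matrix, groups = simulate_genotypes(loci, freqs, {"A": 50}, seed=12)
        assert np.all(matrix.dosages[0] == 0)
        assert np.all(matrix.dosages[1] == 2)

    def test_hardy_weinberg_proportions(self):
        loci = simulate_svs(make_layout(), 1, seed=13)
        freqs = {"A": np.array([0.5])}
        matrix, _ = simulate_genotypes(loci, freqs, {"A": 1000}, seed=14)
        counts = np.bincount(matrix.dosages[0], minlength=3)
        expected = np.array([250, 500, 250])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=2) > 0.001


class TestCallerEmulation:
    @pytest.fixture(scope="class")
    def cohort(self):
        layout = make_layout()
        loci = simulate_svs(layout, 400, seed=15)
        _, freqs = simulate_group_frequencies(400, ["A"], F=0.02, seed=16)
        matrix, _ = simulate_genotypes(loci, freqs, {"A": 6}, seed=17)
        return layout, loci, matrix

    def test_noise_free_callers_emit_truth_exactly(self, cohort):
        layout, loci, matrix = cohort
        out = simulate_caller_callsets(
            loci, matrix.dosages, matrix.individuals,
            jitter_sd=0.0, dropout=0.0, genotype_error=0.0, seed=18, layout=layout,
        )
        carriers = int((matrix.dosages[:, 0] >= 1).sum())
        calls = out[matrix.individuals[0]]["caller1"]
        assert len(calls) == carriers
        for c in calls:
            truth = next(r for r in loci if c.id.startswith(r.id))
            assert (c.start, c.end) == (truth.start, truth.end)

    def test_full_dropout_for_one_caller(self, cohort):
        layout, loci, matrix = cohort
        out = simulate_caller_callsets(
            loci, matrix.dosages, matrix.individuals,
            dropout=[1.0, 0.0, 0.0], seed=19, layout=layout,
        )
        assert all(out[ind]["caller1"] == [] for ind in matrix.individuals)

    def test_jitter_preserves_length(self, cohort):
        layout, loci, matrix = cohort
        out = simulate_caller_callsets(
            loci, matrix.dosages, matrix.individuals, jitter_sd=200.0,
            seed=20, layout=layout,
        )
        truth_by_id = {r.id: r for r in loci}
        for c in out[matrix.individuals[0]]["caller2"]:
            assert c.length == truth_by_id[c.id.rsplit(".", 1)[0]].length

    def test_excessive_jitter_rejected(self, cohort):
        layout, loci, matrix = cohort
        with pytest.raises(ValueError):
            simulate_caller_callsets(loci, matrix.dosages, matrix.individuals,
                                     jitter_sd=500.0, seed=0)


class TestAnnotations:
    def test_repeats_nonoverlapping_and_in_bounds(self, layout):
        repeats, genes = simulate_annotations(layout, seed=21)
        for chrom, g in repeats.table.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].values[1:] >= g["end"].values[:-1]).all()
            assert g["end"].max() <= layout.length(str(chrom))

    def test_class_mix_recovered(self, layout):
        repeats, _ = simulate_annotations(layout, seed=22)
        shares = repeats.table["repeat_class"].value_counts(normalize=True)
        for cls, target in DEFAULT_REPEAT_MIX.items():
            if target > 0.05:
                assert shares[cls] == pytest.approx(target, abs=0.05)

    def test_pure_class_mix(self, layout):
        repeats, _ = simulate_annotations(layout, classes_mix={"Simple": 1.0}, seed=23)
        assert (repeats.table["repeat_class"] == "Simple").all()


class TestPhenotypeModel:
    def test_all_zero_components_give_constant_trait(self):
        matrix = simulate_neutral_spectrum(50, 100, seed=24)
        table, _ = simulate_phenotypes(
            matrix, [TraitModel(name="t", h2=0.0, baseline=5.0, noise_sd=0.0)], seed=25
        )
        assert np.allclose(table["t"], 5.0)

    def test_variance_decomposition_matches_configuration(self):
        rng = np.random.default_rng(26)
        from tests.conftest import make_matrix

        matrix = make_matrix(rng.binomial(2, 0.5, (300, 1000)).astype(np.int16))
        model = TraitModel(name="t", h2=0.4, focal={5: (0.2, 1.0)})
        table, effects = simulate_phenotypes(matrix, [model], seed=27)
        y = table["t"].to_numpy()
        x = matrix.dosages[5].astype(float)
        focal_part = effects["t"][5] * (x - x.mean())
        assert focal_part.var(ddof=1) == pytest.approx(0.2, rel=0.1)
        assert y.var(ddof=1) == pytest.approx(1.0, rel=0.1)

    def test_focal_dosage_groups_differ_by_twice_the_effect(self):
        rng = np.random.default_rng(28)
        from tests.conftest import make_matrix

        matrix = make_matrix(rng.binomial(2, 0.5, (50, 400)).astype(np.int16))
        model = TraitModel(name="t", h2=0.0, focal={0: (0.5, 1.0)}, noise_sd=0.0)
        table, effects = simulate_phenotypes(matrix, [model], seed=29)
        y = table["t"].to_numpy()
        x = matrix.dosages[0]
        gap = y[x == 2].mean() - y[x == 0].mean()
        assert gap == pytest.approx(2 * effects["t"][0], rel=1e-9)

    def test_overcommitted_variance_is_an_error(self):
        with pytest.raises(ValueError):
            TraitModel(name="t", h2=0.8, focal={0: (0.3, 1.0)})


class TestTracks:
    def test_doubling_speed_halves_duration(self):
        from migrasv.phenotypes import route_fraction_series, timing_and_duration

        def bird(speed):
            spec = RouteSpec("b", "M", (48.5, 13.0),
                             rhumb_destination((48.5, 13.0), 200.0, 2000.0),
                             dt.date(2020, 9, 10), speed)
            return simulate_tracks([spec], seed=30)[0]

        slow = timing_and_duration(route_fraction_series(bird(50.0), "fall"))
        fast = timing_and_duration(route_fraction_series(bird(100.0), "fall"))
        assert slow.duration_days == pytest.approx(2 * fast.duration_days, abs=2)

    def test_noisy_timing_recovery_within_one_day(self):
        import math

        from migrasv.phenotypes import great_circle_distance, route_fraction_series, timing_and_duration

        rng = np.random.default_rng(31)
        specs = []
        for i in range(100):
            breeding = (float(rng.uniform(46, 52)), float(rng.uniform(8, 16)))
            wintering = rhumb_destination(
                breeding, float(rng.uniform(170, 230)), float(rng.uniform(1500, 2500))
            )
            specs.append(RouteSpec(
                bird_id=f"b{i}", sex="M", breeding=breeding, wintering=wintering,
                depart_fall=dt.date(2020, 9, 1) + dt.timedelta(days=int(rng.integers(0, 15))),
                speed_km_per_day=float(rng.uniform(80, 120)),
            ))
        birds = simulate_tracks(specs, position_noise_km=50.0, seed=32)
        hits = 0
        for spec, bird in zip(specs, birds):
            gc = great_circle_distance(spec.breeding, spec.wintering)
            T = max(1, math.ceil(gc / spec.speed_km_per_day - 1e-9))
            expected = spec.depart_fall + dt.timedelta(days=math.ceil(0.5 * T))
            res = timing_and_duration(route_fraction_series(bird, "fall"))
            if res.timing is not None and abs((res.timing - expected).days) <= 1:
                hits += 1
        assert hits >= 95

    def test_regenerate_twice_equality(self):
        spec = RouteSpec("b", "F", (48.0, 13.0), (35.0, 0.0), dt.date(2020, 9, 5), 90.0)
        a = simulate_tracks([spec], position_noise_km=30.0, seed=33)
        b = simulate_tracks([spec], position_noise_km=30.0, seed=33)
        assert a == b


class TestBlackcapProfile:
    def test_profile_shape_and_truth(self, tmp_path):
        truth = blackcap_profile(seed=2, n_loci=800, out_dir=tmp_path / "sim")
        assert truth.matrix.n_individuals == 79
        assert truth.matrix.n_loci == 800
        focal = next(r for r in truth.loci if r.id == truth.focal_id)
        assert focal.svtype == "DEL" and focal.length == 710 and focal.chrom == "chr27"
        se_cols = [i for i, b in enumerate(truth.matrix.individuals)
                   if truth.groups[b] == "SE"]
        se_freq = truth.matrix.dosages[
            [i for i, r in enumerate(truth.loci) if r.id == truth.focal_id][0], se_cols
        ].mean() / 2
        assert se_freq > 0.8  # near-fixed in SE migrants
        for name in ("chroms.tsv", "repeats.bed", "genes.gff3", "birds.csv",
                     "tracks.csv", "truth.json"):
            assert (tmp_path / "sim" / name).exists()
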