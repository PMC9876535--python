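import math

import numpy as np
import pytest

from plinet.connectivity import pli_epoch
from plinet.spectral import band_by_name, bandpass, instantaneous_phase
from plinet.synth import (
    CohortConfig,
    CouplingEdge,
    CouplingSpec,
    EffectSpec,
    apply_effect,
    generate_cohort,
    generate_subject_epochs,
)

THETA = band_by_name("theta")
FS = 500.0


def mean_pli(epochs, band, i, j):
    values = []
    for e in range(epochs.n_epochs):
        phases = instantaneous_phase(bandpass(epochs.data[e], band, FS), band)
        values.append(pli_epoch(phases).weights[i, j])
    return float(np.mean(values))


def pair_spec(kappa, lag=math.pi / 4, noise_sd=0.0):
    return CouplingSpec(
        band=THETA, pairs={(0, 1): CouplingEdge(lag=lag, kappa=kappa)}, noise_sd=noise_sd
    )


class TestGenerateSubjectEpochs:
    def test_perfect_coupling_recovers_pli_near_one(self):
        epochs = generate_subject_epochs(pair_spec(1.0), 8, 1024, FS, seed=5, n_channels=3)
        assert mean_pli(epochs, THETA, 0, 1) > 0.99

    def test_uncoupled_pli_matches_monte_carlo_null_of_same_process(self):
        # band-limited phases are autocorrelated, so the null sits well above
        # the iid-sign chance level; compare against an independent draw of
        # the identical generative process rather than sqrt(2/(pi n))
        epochs = generate_subject_epochs(pair_spec(0.0), 30, 1024, FS, seed=6, n_channels=2)
        null_a = mean_pli(epochs, THETA, 0, 1)
        reference = generate_subject_epochs(pair_spec(0.0), 30, 1024, FS, seed=7, n_channels=2)
        null_b = mean_pli(reference, THETA, 0, 1)
        assert abs(null_a - null_b) < 0.15
        assert null_a < 0.7  # far from coupled behaviour

    def test_same_seed_is_bit_identical(self):
        a = generate_subject_epochs(pair_spec(0.5), 3, 256, FS, seed=42, n_channels=4)
        b = generate_subject_epochs(pair_spec(0.5), 3, 256, FS, seed=42, n_channels=4)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = generate_subject_epochs(pair_spec(0.5), 3, 256, FS, seed=42, n_channels=4)
        b = generate_subject_epochs(pair_spec(0.5), 3, 256, FS, seed=43, n_channels=4)
        assert not np.array_equal(a.data, b.data)

    def test_expected_pli_nondecreasing_in_kappa(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for k, kappa in enumerate(grid):
            epochs = generate_subject_epochs(
                pair_spec(kappa, noise_sd=0.2), 40, 512, FS, seed=100 + k, n_channels=2
            )
            means.append(mean_pli(epochs, THETA, 0, 1))
        diffs = np.diff(means)
        assert np.all(diffs > -0.08)  # nondecreasing up to Monte-Carlo error
        assert means[-1] > means[0] + 0.3

    def test_zero_lag_rejected(self):
        with pytest.raises(ValueError):
            pair_spec(0.5, lag=0.0)

    def test_antiphase_lag_rejected(self):
        with pytest.raises(ValueError):
            pair_spec(0.5, lag=math.pi)

    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pair_spec(1.2)

    def test_out_of_range_channel_rejected(self):
        spec = CouplingSpec(band=THETA, pairs={(0, 9): CouplingEdge(math.pi / 4, 0.5)})
        with pytest.raises(ValueError):
            generate_subject_epochs(spec, 2, 128, FS, seed=0, n_channels=4)

    def test_duplicate_target_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(
                band=THETA,
                pairs={
                    (0, 2): CouplingEdge(math.pi / 4, 0.5),
                    (1, 2): CouplingEdge(math.pi / 4, 0.5),
                },
            )


class TestEffectSpec:
    def test_hub_increment_applied_to_all_incident_pairs(self):
        spec = CouplingSpec(band=THETA, pairs={}, noise_sd=0.1)
        effect = EffectSpec(hub_channels=(0,), coupling_increment=0.6)
        boosted = apply_effect(spec, effect, n_channels=5)
        assert set(boosted.pairs) == {(0, c) for c in range(1, 5)}
        assert all(e.kappa == pytest.approx(0.6) for e in boosted.pairs.values())

    def test_increment_beyond_one_rejected(self):
        spec = CouplingSpec(
            band=THETA, pairs={(0, 1): CouplingEdge(math.pi / 4, 0.7, source=0)}
        )
        effect = EffectSpec(hub_channels=(0,), coupling_increment=0.5)
        with pytest.raises(ValueError):
            apply_effect(spec, effect, n_channels=3)

    def test_background_pair_replaced_by_hub(self):
        spec = CouplingSpec(band=THETA, pairs={(1, 2): CouplingEdge(math.pi / 3, 0.4)})
        effect = EffectSpec(hub_channels=(0,), coupling_increment=0.5)
        boosted = apply_effect(spec, effect, n_channels=3)
        assert (1, 2) not in boosted.pairs
        assert set(boosted.pairs) == {(0, 1), (0, 2)}


class TestGenerateCohort:
    def test_study_sized_metadata(self):
        config = CohortConfig(n_control=58, n_mci=41, seed=1)
        dataset = generate_cohort(config, pair_spec(0.3))
        meta = dataset.metadata
        assert meta["subject"].nunique() == 99
        assert (meta["group"] == "control").sum() == 58
        assert (meta["group"] == "MCI").sum() == 41
        # two timepoints per subject = 198 subject-timepoint records
        records = [(s, tp) for s in meta["subject"] for tp in ("pre", "post")]
        assert len(records) == 198
        assert set(meta["gender"]) <= {"female", "male"}

    def test_covariates_near_design_distributions(self):
        config = CohortConfig(n_control=58, n_mci=41, seed=3)
        meta = generate_cohort(config, pair_spec(0.3)).metadata
        ctl = meta[meta.group == "control"]
        mci = meta[meta.group == "MCI"]
        assert ctl["age"].mean() == pytest.approx(71.1, abs=3.0)
        assert mci["age"].mean() == pytest.approx(73.7, abs=3.5)
        assert ctl["education"].mean() == pytest.approx(15.3, abs=1.2)
        assert (ctl["gender"] == "female").mean() == pytest.approx(0.91, abs=0.15)

    def test_epoch_shapes_and_determinism(self):
        config = CohortConfig(
            n_control=2, n_mci=2, n_epochs_per_subject=3, n_channels=4,
            epoch_samples=256, seed=9,
        )
        dataset = generate_cohort(config, pair_spec(0.5))
        epochs = dataset.subject_epochs("S000", "pre")
        assert epochs.data.shape == (3, 4, 256)
        again = generate_cohort(config, pair_spec(0.5)).subject_epochs("S000", "pre")
        assert np.array_equal(epochs.data, again.data)
        post = dataset.subject_epochs("S000", "post")
        assert not np.array_equal(epochs.data, post.data)

    def test_effect_only_touches_target_cell(self):
        config = CohortConfig(
            n_control=1, n_mci=1, n_epochs_per_subject=2, n_channels=4,
            epoch_samples=256, seed=11,
        )
        effect = EffectSpec(
            target_group="MCI", target_timepoint="post",
            hub_channels=(0,), coupling_increment=0.9,
        )
        plain = generate_cohort(config, pair_spec(0.0))
        dosed = generate_cohort(config, pair_spec(0.0), effect=effect)
        meta = dosed.metadata
        mci = meta.loc[meta.group == "MCI", "subject"].iloc[0]
        ctl = meta.loc[meta.group == "control", "subject"].iloc[0]
        for subject, tp in ((ctl, "pre"), (ctl, "post"), (mci, "pre")):
            assert np.array_equal(
                plain.subject_epochs(subject, tp).data,
                dosed.subject_epochs(subject, tp).data,
            )
        assert not np.array_equal(
            plain.subject_epochs(mci, "post").data,
            dosed.subject_epochs(mci, "post").data,
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_control=0)
        with pytest.raises(ValueError):
            CohortConfig(covariate_params={})
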