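"""Splits, QC, metric identities, RPD categories, protocol and reports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milletnir.constants import AMINO_ACIDS, EAA_MEAN_PERCENT
from milletnir.containers import ReferenceChemistry
from milletnir.evaluation import (
    compute_metrics,
    holdout_split,
    qc_reference,
    rpd_category,
    run_protocol,
    summarize_reference,
    write_report,
)
from milletnir.models import ModelHyperparams
from milletnir.synthetic import generate_reference_chemistry


class TestHoldoutSplit:
    def test_217_gives_163_54(self):
        train, test = holdout_split(217, seed=0)
        assert (len(train), len(test)) == (163, 54)

    def test_minimum_four_samples(self):
        train, test = holdout_split(4, seed=1)
        assert (len(train), len(test)) == (3, 1)
        with pytest.raises(ValueError):
            holdout_split(3)

    def test_deterministic_and_disjoint_complete(self):
        a = holdout_split(100, seed=5)
        b = holdout_split(100, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert set(a[0]) | set(a[1]) == set(range(100))
        assert not set(a[0]) & set(a[1])


class TestQc:
    def test_nominal_pass_rate(self):
        passes = total = 0
        for s in range(100):
            chem = generate_reference_chemistry(n=217, seed=5000 + s)
            rep = qc_reference(chem)
            passes += int(rep["normal"].sum())
            total += len(rep)
        rate = passes / total
        assert 0.88 <= rate <= 0.99  # ~95% at alpha = 0.05

    def test_planted_outlier_flagged(self):
        chem = generate_reference_chemistry(n=100, seed=1)
        contents = chem.contents.copy()
        j = AMINO_ACIDS.index("Thr")
        contents[17, j] = contents[:, j].mean() + 10 * contents[:, j].std()
        chem2 = ReferenceChemistry(chem.sample_ids, contents)
        rep = qc_reference(chem2)
        assert 17 in rep.loc["Thr", "outlier_indices"]

    def test_constant_column_degenerate(self):
        contents = np.abs(np.random.default_rng(0).normal(5, 1, size=(30, 8)))
        contents[:, 0] = 2.0
        chem = ReferenceChemistry([f"s{i}" for i in range(30)], contents)
        rep = qc_reference(chem)
        assert bool(rep.loc["Lys", "degenerate"])


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = compute_metrics(y, y)
        assert (m.r2, m.rmse, m.rpd) == (1.0, 0.0, np.inf)

    def test_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)
        assert m.rpd == pytest.approx(1.0, abs=1e-12)

    def test_printed_rpd_at_r2_08037(self, rng):
        y = rng.normal(size=300)
        resid = rng.normal(size=300)
        resid -= resid.mean()
        # scale residuals so R2 hits the target exactly
        target = 0.8037
        ss_tot = ((y - y.mean()) ** 2).sum()
        resid *= np.sqrt((1 - target) * ss_tot / (resid**2).sum())
        m = compute_metrics(y, y - resid)
        assert m.r2 == pytest.approx(target, abs=1e-12)
        assert round(m.rpd, 4) == 2.2570

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_same_set_identity(self, r2_target):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        resid = rng.normal(size=100)
        ss_tot = ((y - y.mean()) ** 2).sum()
        resid *= np.sqrt((1 - r2_target) * ss_tot / (resid**2).sum())
        m = compute_metrics(y, y - resid)
        assert m.rpd * np.sqrt(1 - m.r2) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_metrics(np.ones(5), np.zeros(5))


class TestRpdCategory:
    @pytest.mark.parametrize(
        "rpd,label",
        [
            (2.2570, "good"),
            (1.6417, "moderate"),
            (1.39, "unable"),
            (2.0, "moderate"),  # boundary: >2 required for good
            (1.4, "unable"),  # boundary: >1.4 required for moderate
        ],
    )
    def test_bands(self, rpd, label):
        assert rpd_category(rpd) == label


class TestSummary:
    def test_printed_means_sum(self):
        contents = np.tile(
            [EAA_MEAN_PERCENT[a] for a in AMINO_ACIDS], (3, 1)
        )
        chem = ReferenceChemistry(["a", "b", "c"], contents)
        table = summarize_reference(chem)
        assert round(table.loc["Total", "mean"], 2) == 38.94

    def test_permutation_invariant(self):
        chem = generate_reference_chemistry(n=30, seed=2)
        perm = np.random.default_rng(1).permutation(30)
        chem_p = ReferenceChemistry(
            [chem.sample_ids[i] for i in perm], chem.contents[perm]
        )
        a = summarize_reference(chem)
        b = summarize_reference(chem_p)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


@pytest.fixture(scope="module")
def protocol_inputs():
    from milletnir.preprocess import preprocess_pipeline
    from milletnir.synthetic import generate_dataset

    chem, spectra = generate_dataset(n=60, seed=8)
    return preprocess_pipeline(spectra), chem


class TestProtocol:
    def test_selection_contract_and_seeds(self, protocol_inputs, tmp_path):
        spectra, chem = protocol_inputs
        result = run_protocol(
            spectra,
            chem,
            target="Ile",
            model_kinds=("PLSR",),
            use_key_wavelengths=False,
            runs=3,
            base_seed=10,
            hyperparams=ModelHyperparams(plsr_ncomp=4),
        )
        vals = result.criterion_values()
        assert result.runs[result.selected_run]["criterion_value"] == vals.max()
        assert [r["seed"] for r in result.runs] == [10, 11, 12]

        json_path, csv_path = write_report(result, tmp_path / "report", {"runs": 3})
        payload = json.loads(json_path.read_text())
        stored = payload["runs"][0]["models"]["PLSR"]["prediction"]["r2"]
        assert stored == result.runs[0]["models"]["PLSR"]["prediction"]["r2"]
        assert csv_path.exists()

    def test_single_run_equals_manual_pipeline(self, protocol_inputs):
        from milletnir.evaluation import holdout_split
        from milletnir.models import fit_model

        spectra, chem = protocol_inputs
        hp = ModelHyperparams(plsr_ncomp=4)
        result = run_protocol(
            spectra,
            chem,
            target="Thr",
            model_kinds=("PLSR",),
            use_key_wavelengths=False,
            runs=1,
            base_seed=3,
            hyperparams=hp,
        )
        y = chem.column("Thr")
        train, test = holdout_split(len(y), seed=3)
        model = fit_model(
            spectra.reflectance[train],
            y[train],
            ModelHyperparams(plsr_ncomp=4, model_kind="PLSR", seed=3),
        )
        pred = model.predict(spectra.reflectance[test])
        manual = compute_metrics(y[test], pred)
        assert result.runs[0]["models"]["PLSR"]["prediction"]["r2"] == pytest.approx(
            manual.r2, abs=1e-12
        )

    def test_key_wavelength_mode_records_selection(self, protocol_inputs):
        spectra, chem = protocol_inputs
        result = run_protocol(
            spectra,
            chem,
            target="Ile",
            model_kinds=("PLSR",),
            use_key_wavelengths=True,
            runs=1,
            base_seed=0,
            hyperparams=ModelHyperparams(plsr_ncomp=2),
            cars_iterations=30,
        )
        rec = result.runs[0]
        assert "selected_wavelengths_nm" in rec
        assert len(rec["selected_indices"]) >= 1
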