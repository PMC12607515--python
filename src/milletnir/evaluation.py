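"""Dataset QC, hold-out splitting, metrics (R2 / RMSE / RPD), the repeated
independent-run protocol, and report writing.

RPD (ratio of performance to deviation) is the standard deviation of the
reference values divided by the RMSE.  With the population (denominator n)
standard deviation and both quantities computed on the same evaluation set,
RPD = (1 - R2)^(-1/2) exactly; the sample (n-1) convention is available by
flag.  Interpretation bands: RPD > 2 good, 1.4 < RPD <= 2 moderate,
RPD <= 1.4 unable to predict.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cars import run_cars
from .containers import ReferenceChemistry, SpectrumSet, align
from .models import ModelHyperparams, fit_model

__all__ = [
    "EvaluationMetrics",
    "holdout_split",
    "qc_reference",
    "compute_metrics",
    "rpd_category",
    "summarize_reference",
    "RunProtocolResult",
    "run_protocol",
    "write_report",
]


@dataclass
class EvaluationMetrics:
    """R2, RMSE and RPD of one model on one evaluation set."""

    r2: float
    rmse: float
    rpd: float
    n: int
    set_label: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def holdout_split(
    n: int, train_fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random 3:1 (by default) partition into training and prediction sets.

    ``|train| = round(train_fraction * n)``; indices are returned sorted.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def qc_reference(chem: ReferenceChemistry, alpha: float = 0.05) -> pd.DataFrame:
    """Per-analyte Shapiro-Wilk normality test and 1.5 IQR boxplot outliers.

    Report only — no samples are removed.  Constant columns are flagged
    ``degenerate`` (normality undefined).
    """
    rows = []
    for name in chem.amino_acid_names:
        x = chem.column(name)
        degenerate = bool(np.ptp(x) == 0)
        if degenerate:
            w, p = np.nan, np.nan
            outliers: list[int] = []
        else:
            w, p = stats.shapiro(x)
            q1, q3 = np.percentile(x, [25, 75])
            iqr = q3 - q1
            mask = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
            outliers = list(np.flatnonzero(mask))
        rows.append(
            {
                "analyte": name,
                "shapiro_w": w,
                "shapiro_p": p,
                "normal": (p > alpha) if not degenerate else False,
                "degenerate": degenerate,
                "n_outliers": len(outliers),
                "outlier_indices": outliers,
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    set_label: str = "",
    population_sd: bool = True,
) -> EvaluationMetrics:
    """R2, RMSE and RPD of predictions against reference values.

    ``population_sd=True`` (default) uses the denominator-n standard
    deviation in RPD, which makes RPD = (1 - R2)^(-1/2) an identity on a
    same-set evaluation.  Perfect predictions report RPD = +inf.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    n = y_true.size
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in y_true: R2 and RPD undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / n))
    sd = float(y_true.std(ddof=0 if population_sd else 1))
    rpd = float(np.inf) if rmse == 0 else sd / rmse
    return EvaluationMetrics(r2=r2, rmse=rmse, rpd=rpd, n=n, set_label=set_label)


def rpd_category(rpd: float) -> str:
    """Interpretation band: >2 good; (1.4, 2] moderate; <=1.4 unable."""
    if rpd > 2.0:
        return "good"
    if rpd > 1.4:
        return "moderate"
    return "unable"


def summarize_reference(chem: ReferenceChemistry) -> pd.DataFrame:
    """Mean/sd/min/max per analyte, plus a Total row whose mean is the sum
    of the per-analyte mean percentages."""
    data = {
        name: chem.column(name) for name in chem.amino_acid_names
    }
    rows = {
        name: {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
        for name, x in data.items()
    }
    df = pd.DataFrame(rows).T
    total = float(df["mean"].sum())
    df.loc["Total"] = {"mean": total, "sd": np.nan, "min": np.nan, "max": np.nan}
    return df


@dataclass
class RunProtocolResult:
    """Outcome of the repeated independent-run protocol."""

    runs: list[dict]
    selected_run: int
    selection_criterion: str
    target: str
    use_key_wavelengths: bool

    @property
    def selected(self) -> dict:
        return self.runs[self.selected_run]

    def criterion_values(self) -> np.ndarray:
        return np.array(
            [r.get("criterion_value", -np.inf) for r in self.runs], dtype=float
        )


def _criterion_value(run: dict, criterion: str) -> float:
    best = -np.inf
    for kind, m in run["models"].items():
        if criterion == "prediction_r2":
            v = m["prediction"]["r2"]
        elif criterion == "prediction_rpd":
            v = m["prediction"]["rpd"]
        else:
            raise ValueError(f"unknown selection criterion {criterion!r}")
        best = max(best, v)
    return best


def run_protocol(
    spectra: SpectrumSet,
    chem: ReferenceChemistry,
    target: str,
    model_kinds: tuple[str, ...] = ("PLSR",),
    use_key_wavelengths: bool = True,
    runs: int = 50,
    base_seed: int = 0,
    hyperparams: ModelHyperparams | None = None,
    cars_iterations: int = 500,
    cars_folds: int = 10,
    selection_criterion: str = "prediction_r2",
) -> RunProtocolResult:
    """Repeated independent runs of split -> (CARS) -> fit -> evaluate.

    Each run r uses seed ``base_seed + r`` for the hold-out split, the CARS
    run and model fitting.  The reported run maximizes the selection
    criterion (default: best prediction-set R2 across the fitted models);
    the full per-run distribution is retained.  Failures inside a run are
    recorded and the protocol continues.
    """
    align(spectra, chem)
    y_all = chem.column(target)
    X_all = spectra.reflectance
    results: list[dict] = []
    for r in range(runs):
        seed = base_seed + r
        record: dict = {"run": r, "seed": seed}
        try:
            train, test = holdout_split(len(y_all), seed=seed)
            if use_key_wavelengths:
                cars_res = run_cars(
                    X_all[train],
                    y_all[train],
                    n_iterations=cars_iterations,
                    k=cars_folds,
                    seed=seed,
                    wavelengths=spectra.wavelengths,
                )
                idx = cars_res.selected_indices
                record["selected_indices"] = idx.tolist()
                record["selected_wavelengths_nm"] = (
                    spectra.wavelengths[idx].tolist()
                )
                record["cars_best_rmsecv"] = cars_res.best_rmsecv
            else:
                idx = np.arange(X_all.shape[1])
            record["models"] = {}
            for kind in model_kinds:
                hp = hyperparams or ModelHyperparams()
                hp = ModelHyperparams(**{**asdict(hp), "model_kind": kind, "seed": seed})
                model = fit_model(X_all[np.ix_(train, idx)], y_all[train], hp)
                m_train = compute_metrics(
                    y_all[train], model.predict(X_all[np.ix_(train, idx)]), "training"
                )
                m_pred = compute_metrics(
                    y_all[test], model.predict(X_all[np.ix_(test, idx)]), "prediction"
                )
                record["models"][kind] = {
                    "training": m_train.as_dict(),
                    "prediction": m_pred.as_dict(),
                    "rpd_category": rpd_category(m_pred.rpd),
                }
            record["criterion_value"] = _criterion_value(record, selection_criterion)
        except Exception as exc:  # noqa: BLE001 - per-run failures are data
            record["error"] = f"{type(exc).__name__}: {exc}"
        results.append(record)
    ok = [i for i, rec in enumerate(results) if "error" not in rec]
    if not ok:
        raise RuntimeError("every protocol run failed")
    selected = max(ok, key=lambda i: results[i]["criterion_value"])
    return RunProtocolResult(
        runs=results,
        selected_run=selected,
        selection_criterion=selection_criterion,
        target=target,
        use_key_wavelengths=use_key_wavelengths,
    )


def _config_fingerprint(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(
    result: RunProtocolResult, path_prefix: str | Path, config: dict | None = None
) -> tuple[Path, Path]:
    """Write the protocol result as JSON (full) and CSV (per-run metrics).

    Returns (json_path, csv_path).  The JSON round-trips every metric value
    bit-exactly (floats serialized at full precision).
    """
    path_prefix = Path(path_prefix)
    payload = {
        "target": result.target,
        "use_key_wavelengths": result.use_key_wavelengths,
        "selection_criterion": result.selection_criterion,
        "selected_run": result.selected_run,
        "config_fingerprint": _config_fingerprint(config or {}),
        "config": config or {},
        "runs": result.runs,
    }
    json_path = path_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=1, default=str))

    rows = []
    for rec in result.runs:
        if "error" in rec:
            rows.append({"run": rec["run"], "seed": rec["seed"], "error": rec["error"]})
            continue
        for kind, m in rec["models"].items():
            for split in ("training", "prediction"):
                rows.append(
                    {
                        "run": rec["run"],
                        "seed": rec["seed"],
                        "model": kind,
                        "set": split,
                        **{k: m[split][k] for k in ("r2", "rmse", "rpd", "n")},
                    }
                )
    csv_path = path_prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return json_path, csv_path
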