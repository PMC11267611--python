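"""Fit LFER sensitivities (alpha, beta, intercept) by multiple linear regression.

The barrier model ``dH_act = c0 + alpha*dH_r + beta*chi`` is linear in its
parameters, so ordinary least squares on the design ``[1, dH_r, chi]`` (plus
an optional ``dH_r**2`` column) recovers them directly. Fits are per reagent
class by default, since the sensitivities are class-specific; R-squared is the
in-sample coefficient of determination and RMSE the population-form
root-mean-square residual, both over the fitted records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import ReactionRecord
from .models import BarrierDecomposition, LFERParameters, decompose, strain_deloc_barrier

__all__ = [
    "FitResult",
    "CollinearityError",
    "fit_lfer",
    "predict_barriers",
    "compare_models",
    "decompose_vs_reference",
    "summary_table",
]

DESCRIPTORS = ("chi_nbo", "chi_rho", "n3", "none")


class CollinearityError(ValueError):
    """Design matrix is rank deficient (perfectly collinear columns)."""


@dataclass
class FitResult:
    """OLS fit of one barrier model on one set of records."""

    params: LFERParameters
    r_squared: float
    rmse: float
    residuals: np.ndarray
    n_records: int
    descriptor_used: str
    quadratic: bool = False
    quadratic_coef: float | None = None
    rmse_dof: float | None = None  #: n-p denominator variant
    record_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "intercept": self.params.intercept,
                "r2": self.r_squared,
                "rmse": self.rmse,
                "n": self.n_records,
                "descriptor": self.descriptor_used,
                "quadratic": self.quadratic,
                "quadratic_coef": self.quadratic_coef,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # re-validation already happened at fit time
            params = LFERParameters(
                alpha=d["alpha"], beta=d["beta"], intercept=d["intercept"]
            )
        return cls(
            params=params,
            r_squared=d["r2"],
            rmse=d["rmse"],
            residuals=np.array([]),
            n_records=d["n"],
            descriptor_used=d["descriptor"],
            quadratic=d.get("quadratic", False),
            quadratic_coef=d.get("quadratic_coef"),
        )


def _fitting_rows(records, descriptor: str):
    rows = []
    for r in records:
        if r.dH_act is None:
            continue
        if descriptor == "none":
            rows.append((r, 0.0))
            continue
        value = r.descriptor(descriptor)
        if value is None:
            continue
        rows.append((r, float(value)))
    return rows


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending pair for the error message
        for a in range(X.shape[1]):
            for b in range(a + 1, X.shape[1]):
                sub = X[:, [a, b]]
                if np.linalg.matrix_rank(sub) < 2:
                    raise CollinearityError(
                        f"design columns {names[a]!r} and {names[b]!r} are "
                        "perfectly collinear; the model is unidentifiable"
                    )
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]})"
        )


def fit_lfer(
    records,
    descriptor: str = "chi_nbo",
    include_quadratic: bool = False,
    allow_mixed_reagents: bool = False,
) -> FitResult:
    """OLS fit of dH_act on [1, dH_r, descriptor] (+ dH_r**2 if requested).

    ``descriptor`` is one of chi_nbo | chi_rho | n3 | none ("none" fits the
    two-parameter BEP model). Records lacking dH_act or the chosen descriptor
    are excluded; at least three usable records are required. Reagent classes
    are fitted separately unless ``allow_mixed_reagents`` is set.
    """
    if descriptor not in DESCRIPTORS:
        raise ValueError(f"descriptor must be one of {DESCRIPTORS}, got {descriptor!r}")
    rows = _fitting_rows(records, descriptor)
    if len(rows) < 3:
        raise ValueError(
            f"need at least 3 records with dH_act and {descriptor!r}, "
            f"got {len(rows)}"
        )
    reagents = {r.reagent for r, _ in rows}
    if len(reagents) > 1 and not allow_mixed_reagents:
        raise ValueError(
            f"records mix reagent classes {sorted(reagents)}; sensitivities are "
            "class-specific -- pass allow_mixed_reagents=True to override"
        )

    y = np.array([r.dH_act for r, _ in rows], dtype=float)
    dhr = np.array([r.dH_r for r, _ in rows], dtype=float)
    cols = [np.ones_like(dhr), dhr]
    names = ["intercept", "dH_r"]
    if descriptor != "none":
        cols.append(np.array([chi for _, chi in rows], dtype=float))
        names.append(descriptor)
    if include_quadratic:
        cols.append(dhr**2)
        names.append("dH_r^2")
    X = np.column_stack(cols)
    _check_rank(X, names)

    ols = sm.OLS(y, X).fit()
    coef = ols.params
    resid = np.asarray(ols.resid)
    n, p = X.shape
    rmse = float(np.sqrt(np.mean(resid**2)))
    rmse_dof = float(np.sqrt(np.sum(resid**2) / (n - p))) if n > p else None

    beta = float(coef[2]) if descriptor != "none" else None
    quad_coef = float(coef[-1]) if include_quadratic else None
    params = LFERParameters(alpha=float(coef[1]), beta=beta, intercept=float(coef[0]))
    return FitResult(
        params=params,
        r_squared=float(ols.rsquared),
        rmse=rmse,
        residuals=resid,
        n_records=n,
        descriptor_used=descriptor,
        quadratic=include_quadratic,
        quadratic_coef=quad_coef,
        rmse_dof=rmse_dof,
        record_ids=[r.id for r, _ in rows],
    )


def predict_barriers(records, fit: FitResult) -> list[tuple[str, float]]:
    """Apply a fitted model to records, returning (id, predicted dH_act).

    Every record must carry the descriptor the fit used (trivially satisfied
    for BEP fits); offending ids are reported together.
    """
    missing = []
    if fit.descriptor_used != "none":
        for r in records:
            if r.descriptor(fit.descriptor_used) is None:
                missing.append(r.id)
    if missing:
        raise ValueError(
            f"records missing descriptor {fit.descriptor_used!r}: {missing}"
        )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-barrier flag not useful in bulk
        for r in records:
            chi = r.descriptor(fit.descriptor_used) or 0.0
            value = strain_deloc_barrier(r.dH_r, float(chi), fit.params)
            if fit.quadratic and fit.quadratic_coef is not None:
                value += fit.quadratic_coef * r.dH_r**2
            out.append((r.id, float(value)))
    return out


def compare_models(records, descriptors=("none", "chi_nbo")) -> dict[str, FitResult]:
    """Fit one model per descriptor on identical records; "none" is BEP.

    To keep the record set identical across models, only records carrying
    every requested descriptor (and dH_act) enter any fit.
    """
    needed = [d for d in descriptors if d != "none"]
    usable = [
        r
        for r in records
        if r.dH_act is not None and all(r.descriptor(d) is not None for d in needed)
    ]
    return {d: fit_lfer(usable, descriptor=d) for d in descriptors}


def summary_table(results: dict[str, FitResult]) -> pd.DataFrame:
    """Aligned fit statistics, one row per model (for model comparison)."""
    rows = []
    for name, fr in results.items():
        rows.append(
            {
                "descriptor": name,
                "alpha": fr.params.alpha,
                "beta": fr.params.beta,
                "intercept": fr.params.intercept,
                "r2": fr.r_squared,
                "rmse": fr.rmse,
                "n": fr.n_records,
            }
        )
    return pd.DataFrame(rows)


def decompose_vs_reference(
    records, fit: FitResult, reference_id: str
) -> list[BarrierDecomposition]:
    """Strain/delocalization split of each record's barrier vs a reference.

    For each record: strain = alpha*(dH_r - dH_r_ref), deloc =
    beta*(chi - chi_ref). The reference decomposed against itself is exactly
    zero in both terms.
    """
    ref = None
    for r in records:
        if r.id == reference_id:
            ref = r
            break
    if ref is None:
        raise KeyError(f"reference id {reference_id!r} not among the records")
    if fit.descriptor_used == "none":
        chi_of = lambda r: 0.0  # noqa: E731 - BEP has no delocalization term
    else:
        def chi_of(r):
            v = r.descriptor(fit.descriptor_used)
            if v is None:
                raise ValueError(
                    f"record {r.id!r} missing descriptor {fit.descriptor_used!r}"
                )
            return float(v)
    ref_chi = chi_of(ref)
    return [
        decompose(
            r.dH_r - ref.dH_r,
            chi_of(r) - ref_chi,
            fit.params,
            reference_id=reference_id,
            compound_id=r.id,
        )
        for r in records
    ]


def loo_diagnostics(records, descriptor: str = "chi_nbo") -> pd.DataFrame:
    """Leave-one-out prediction errors (diagnostic only, not used in fitting)."""
    rows = _fitting_rows(records, descriptor)
    usable = [r for r, _ in rows]
    out = []
    for i, held in enumerate(usable):
        train = usable[:i] + usable[i + 1 :]
        fr = fit_lfer(train, descriptor=descriptor)
        (_, pred), = predict_barriers([held], fr)
        out.append({"id": held.id, "observed": held.dH_act, "loo_pred": pred,
                    "loo_error": pred - held.dH_act})
    return pd.DataFrame(out)
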