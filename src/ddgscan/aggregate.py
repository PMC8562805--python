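"""Ensemble averaging and the error-decomposition model.

Averaging rationale: a ddG predicted from a single coordinate set behaves
like a draw from a distribution with mean mu (set by the energy function)
and spread sigma (set by coordinate-set idiosyncrasies).  Averaging n
independent coordinate sets keeps the mean and shrinks the spread to
sigma/sqrt(n) — the standard error reported here.  The systematic part of
the error (force-field bias, experimental gold-standard error) does not
average away; the two components are separated by fitting

    rmse(n)^2 = sigma_single^2 / n + sigma_systematic^2

which is linear in 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ddg import DdgResult
from .mutmap import MutationSpec

__all__ = ["EnsembleReport", "ErrorModelFit", "average_ensemble", "fit_error_model"]


@dataclass
class EnsembleReport:
    """Per-homolog ddG values and their ensemble summary (kcal/mol)."""

    mutation: Optional[MutationSpec]
    per_structure: list[DdgResult]
    mean_ddg: float
    n_used: int
    sample_sd: Optional[float]  # None when n_used == 1
    standard_error: Optional[float]  # sample_sd / sqrt(n_used)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "structure_id": r.structure_id,
                "mutation": r.mutation.text() if r.mutation else "",
                "ddg_kcal_mol": r.ddg if r.ddg is not None else "",
                "backend": r.backend,
                "status": r.status,
                "detail": r.detail,
            }
            for r in self.per_structure
        ]
        return pd.DataFrame(rows)

    def summary_row(self) -> dict:
        return {
            "mutation": self.mutation.text() if self.mutation else "",
            "mean_ddg_kcal_mol": self.mean_ddg,
            "n_used": self.n_used,
            "sample_sd": self.sample_sd if self.sample_sd is not None else "",
            "standard_error": (
                self.standard_error if self.standard_error is not None else ""
            ),
        }


def average_ensemble(
    results: Sequence[DdgResult], mutation: Optional[MutationSpec] = None
) -> EnsembleReport:
    """Plain arithmetic mean of the usable per-structure ddG values.

    Results with any non-``ok`` status are listed in the report but excluded
    from the mean.  Unweighted by design: every accepted homolog counts the
    same.  Raises when no usable result exists.
    """
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise ValueError("no usable homologs: zero ok ddG results")
    values = np.array([r.ddg for r in ok], dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else None
    return EnsembleReport(
        mutation=mutation if mutation is not None else ok[0].mutation,
        per_structure=list(results),
        mean_ddg=float(values.mean()),
        n_used=n,
        sample_sd=sd,
        standard_error=(sd / sqrt(n)) if sd is not None else None,
    )


@dataclass
class ErrorModelFit:
    """Decomposition of prediction error into averaging-reducible and
    systematic components."""

    sigma_single: float  # kcal/mol; shrinks as 1/sqrt(n)
    sigma_systematic: float  # kcal/mol; floor that averaging cannot remove
    residuals: dict[int, float] = field(default_factory=dict)

    def predicted_rmse(self, n: int) -> float:
        return sqrt(self.sigma_single**2 / n + self.sigma_systematic**2)


def fit_error_model(points: Sequence[tuple[int, float]]) -> ErrorModelFit:
    """Fit rmse(n)^2 = sigma_single^2 / n + sigma_systematic^2.

    ``points`` are (number of structures averaged, observed RMSE) pairs.
    The model is linear in 1/n, so an ordinary least-squares fit of rmse^2
    against 1/n gives sigma_single^2 as the slope and sigma_systematic^2 as
    the intercept; negative estimates are clipped to zero before taking
    square roots.  Requires at least two distinct n.
    """
    pts = [(int(n), float(r)) for n, r in points]
    if any(n < 1 for n, _ in pts):
        raise ValueError("structure counts must be >= 1")
    if len({n for n, _ in pts}) < 2:
        raise ValueError("need at least two distinct structure counts to fit")
    inv_n = np.array([1.0 / n for n, _ in pts])
    y = np.array([r**2 for _, r in pts])
    X = np.column_stack([inv_n, np.ones_like(inv_n)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma_single = sqrt(max(slope, 0.0))
    sigma_systematic = sqrt(max(intercept, 0.0))
    fit = ErrorModelFit(sigma_single=sigma_single, sigma_systematic=sigma_systematic)
    for n, r in pts:
        fit.residuals[n] = r - fit.predicted_rmse(n)
    return fit
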