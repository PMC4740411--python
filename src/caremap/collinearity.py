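"""Variance inflation factors and iterative collinearity screening.

``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from an ordinary
least-squares regression of covariate j on all the other covariates plus an
intercept.  A VIF above 2.5 is treated as a multicollinearity concern
(Allison's rule of thumb), and :func:`screen` removes the worst offender,
recomputes, and repeats until every retained covariate is below the
threshold.  For exactly two covariates with sample correlation r the closed
form is ``VIF = 1 / (1 - r^2)`` for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: R^2 this close to 1 is reported as an infinite VIF (exact dependence).
_R2_SINGULAR = 1.0 - 1e-12


@dataclass(frozen=True)
class VIFReport:
    """Outcome of a screening pass.

    ``vif`` holds the final VIFs of the retained covariates; ``dropped``
    lists removed covariates in removal order with the VIF each had at its
    removal step; ``pairwise_r`` is the Pearson correlation matrix of the
    *original* covariate set.
    """

    vif: dict[str, float]
    dropped: tuple[tuple[str, float], ...]
    pairwise_r: pd.DataFrame
    threshold: float

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.vif)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "vif": dict(self.vif),
            "dropped": [[name, v] for name, v in self.dropped],
            "pairwise_r": {
                "names": list(self.pairwise_r.columns),
                "matrix": self.pairwise_r.to_numpy().tolist(),
            },
        }


def _as_matrix(x, names):
    if isinstance(x, pd.DataFrame):
        names = list(x.columns) if names is None else list(names)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(x.shape[1])]
    return x, list(names)


def vif(x, names: list[str] | None = None) -> dict[str, float]:
    """VIF of each column of the covariate matrix ``x``.

    Exact linear dependence is reported as ``inf``, not raised; a constant
    column (zero variance) is an error because its auxiliary R^2 is
    meaningless.
    """
    x, names = _as_matrix(x, names)
    n, p = x.shape
    if p < 2:
        raise ValidationError("VIF needs at least two covariates")
    if n <= p:
        raise ValidationError("VIF needs more observations than covariates")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError(
            f"constant covariate column {names[int(np.argmax(sd == 0))]!r}"
        )
    out = {}
    intercept = np.ones((n, 1))
    for j in range(p):
        yj = x[:, j]
        others = np.hstack([intercept, np.delete(x, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst
        out[names[j]] = float("inf") if r2 >= _R2_SINGULAR else 1.0 / (1.0 - r2)
    return out


def screen(
    x,
    names: list[str] | None = None,
    threshold: float = 2.5,
) -> tuple[VIFReport, pd.DataFrame]:
    """Iteratively drop the covariate with the greatest VIF above threshold.

    Ties are broken by column order (the earlier column wins, i.e. is
    dropped).  Returns the report and the reduced covariate matrix as a
    DataFrame.  Screening its own output is a no-op (idempotence).
    """
    x, names = _as_matrix(x, names)
    full = pd.DataFrame(x, columns=names)
    pairwise = full.corr(method="pearson")
    keep = list(names)
    dropped: list[tuple[str, float]] = []
    while True:
        if len(keep) < 2:
            raise ValidationError(
                "screening removed all but one covariate; the covariate set "
                "is degenerate at this threshold"
            )
        v = vif(full[keep], keep)
        worst = max(v.values())
        if worst <= threshold:
            break
        # first column attaining the max wins the tie
        name = next(k for k in keep if v[k] == worst)
        keep.remove(name)
        dropped.append((name, worst))
    report = VIFReport(
        vif={k: v[k] for k in keep},
        dropped=tuple(dropped),
        pairwise_r=pairwise,
        threshold=float(threshold),
    )
    return report, full[keep].copy()
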