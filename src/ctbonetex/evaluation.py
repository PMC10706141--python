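"""Agreement metrics between predicted and reference bone measures.

Pearson correlation, mean absolute error, mean squared error, and a
two-sided paired t-test for systematic bias.  Because the linear fits
carry a bias term, in-sample residuals average exactly zero and the
paired t-test returns p = 1 — the signature of an unbiased estimator
evaluated on its own training sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError
from .regression import LinearModel

__all__ = [
    "EvalReport",
    "pearson_cc",
    "mae",
    "mse",
    "paired_t_test",
    "evaluate_model",
    "plot_predictions",
]


@dataclass(frozen=True)
class EvalReport:
    """The evaluation battery for one model on one case set."""

    cc: float
    mae: float
    mse: float
    t_stat: float
    p_value: float
    n: int
    target_name: str
    n_nonzero: Optional[int] = None
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise ValueError("|cc| must be <= 1")
        if self.mae < 0 or self.mse < 0:
            raise ValueError("errors must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pair(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ConfigurationError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def pearson_cc(a, b) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    a, b = _pair(a, b)
    if a.size < 3:
        raise ConfigurationError("correlation needs n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ConfigurationError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(a, b).statistic)


def mae(pred, ref) -> float:
    """Mean absolute error."""
    pred, ref = _pair(pred, ref)
    if pred.size < 1:
        raise ConfigurationError("mae needs n >= 1")
    return float(np.mean(np.abs(pred - ref)))


def mse(pred, ref) -> float:
    """Mean squared error."""
    pred, ref = _pair(pred, ref)
    if pred.size < 1:
        raise ConfigurationError("mse needs n >= 1")
    return float(np.mean((pred - ref) ** 2))


def paired_t_test(pred, ref) -> Tuple[float, float]:
    """Two-sided paired t-test of pred − ref against zero mean.

    One-sample t on the differences with n − 1 degrees of freedom.
    Degenerate conventions: all differences identical and zero → (0, 1);
    identical but nonzero → (±inf, 0), the bias being certain.
    """
    pred, ref = _pair(pred, ref)
    if pred.size < 2:
        raise ConfigurationError("paired t-test needs n >= 2")
    d = pred - ref
    sd = d.std(ddof=1)
    if sd == 0.0:
        m = d.mean()
        if m == 0.0:
            return 0.0, 1.0
        return float(np.sign(m) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * sps.t.sf(abs(t), df=d.size - 1))
    return t, p


def evaluate_model(model: LinearModel, X_raw, refs) -> EvalReport:
    """Predict with ``model`` and compute the full metric battery."""
    refs = np.asarray(refs, dtype=float).ravel()
    pred = model.predict(X_raw)
    t, p = paired_t_test(pred, refs)
    report = EvalReport(
        cc=pearson_cc(pred, refs),
        mae=mae(pred, refs),
        mse=mse(pred, refs),
        t_stat=t,
        p_value=p,
        n=int(refs.size),
        target_name=model.target_name,
        n_nonzero=model.n_nonzero,
        lam=model.lam,
    )
    if report.mae > np.sqrt(report.mse) + 1e-12:
        raise AssertionError("MAE exceeded RMSE — metric implementation error")
    return report


def plot_predictions(
    pred, ref, path: str | Path, target_name: str = "BMC", units: str = "g"
) -> Path:
    """Scatter of predicted vs reference values with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred, ref = _pair(pred, ref)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, pred, s=14, alpha=0.6, edgecolors="none")
    lo = float(min(ref.min(), pred.min()))
    hi = float(max(ref.max(), pred.max()))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    r = pearson_cc(pred, ref)
    ax.set_xlabel(f"reference {target_name} ({units})")
    ax.set_ylabel(f"predicted {target_name} ({units})")
    ax.set_title(f"{target_name}: r = {r:.3f}, MAE = {mae(pred, ref):.3f} {units}")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
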