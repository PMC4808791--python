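"""Linear model of optimal mismatch rate vs divergence, and the decision flow.

The assembly strategy decision works in three steps: (1) if the species'
own reference genome exists, use reference-based assembly; (2) otherwise,
take the genetic distance to the closest sequenced relative from the most
trustworthy available marker (orthologous transcriptome, then 16S rRNA,
then D-loop) and compare it with that marker's distance bound; (3) within
the bound, predict the optimal mapping mismatch rate from a linear model
trained on virtual-genome experiments and recommend pseudo-reference-based
assembly (PRA) with that allowance — unless the predicted rate exceeds the
rate bound, in which case de novo assembly is the better choice.

The shipped default model is a *procedure*, not hard-coded coefficients:
a seeded virtual-genome run bundled as a TSV of (mutation rate, optimal
mismatch rate) points, re-fitted at load time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np


class Strategy(str, Enum):
    REFERENCE_BASED = "REFERENCE_BASED"
    PRA = "PRA"
    DE_NOVO = "DE_NOVO"


MARKER_PREFERENCE = ("ortholog", "16s", "dloop")


@dataclass(frozen=True)
class DecisionThresholds:
    """Distance bounds per marker and the mismatch-rate bound (percent).

    Defaults are the published operating points: PRA outperforms de novo
    within ortholog distance 0.101 (16S 0.189, D-loop 0.363) and optimal
    mismatch rate 14.44%.  Boundaries are inclusive: at exactly the bound,
    PRA is still recommended.
    """

    p_ortholog: float = 0.101
    p_16s: float = 0.189
    p_dloop: float = 0.363
    max_mismatch_rate: float = 14.44
    preference: tuple[str, ...] = MARKER_PREFERENCE
    ambiguous_warn: float = 0.05

    def bound_for(self, marker: str) -> float:
        return {"ortholog": self.p_ortholog,
                "16s": self.p_16s,
                "dloop": self.p_dloop}[marker]


DEFAULT_THRESHOLDS = DecisionThresholds()


@dataclass
class LinearModel:
    """OLS line y = slope·x + intercept with fit diagnostics.

    x is a genetic distance or virtual mutation rate (fraction); y is the
    optimal mismatch rate in percent.  rmse = sqrt(mean squared residual).
    """

    slope: float
    intercept: float
    r2: float
    rmse: float
    training_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def x_range(self) -> tuple[float, float]:
        xs = [x for x, _ in self.training_points]
        return (min(xs), max(xs)) if xs else (float("nan"), float("nan"))

    def to_json(self) -> str:
        return json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r2": self.r2, "rmse": self.rmse,
            "points": self.training_points,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        obj = json.loads(text)
        return cls(obj["slope"], obj["intercept"], obj["r2"], obj["rmse"],
                   [tuple(p) for p in obj["points"]])


@dataclass
class Prediction:
    """Predicted optimal mismatch rate (%) and, given L, the integer N."""

    rate: float
    n_mismatches: int | None = None
    extrapolated: bool = False


@dataclass
class Decision:
    strategy: Strategy
    predicted_mismatch_rate: float | None
    rationale: str
    warnings: list[str] = field(default_factory=list)
    marker: str | None = None
    distance: float | None = None


def fit_linear(points) -> LinearModel:
    """Ordinary least squares fit of y on x.

    r² = 1 − SS_res/SS_tot (defined as 1 when SS_tot = 0 and the fit is
    exact); rmse is over the training points.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 2:
        raise ValueError("fit_linear needs at least 2 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("fit_linear: all x values equal")
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if np.isclose(ss_res, 0.0) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return LinearModel(float(slope), float(intercept), float(r2), rmse, pts)


def predict_mismatch(model: LinearModel, x: float,
                     read_length: int | None = None) -> Prediction:
    """slope·x + intercept, clamped to [0, 100] percent.

    Values of x outside the training range are allowed but flagged (and
    warned), since the linearity is only established inside it.
    """
    if x < 0:
        raise ValueError(f"distance/mutation rate must be >= 0, got {x}")
    raw = model.slope * x + model.intercept
    rate = float(min(100.0, max(0.0, raw)))
    lo, hi = model.x_range
    extrapolated = bool(model.training_points) and not (lo <= x <= hi)
    if extrapolated:
        warnings.warn(
            f"x={x:g} outside training range [{lo:g}, {hi:g}]; extrapolating"
        )
    n = int(round(rate * read_length / 100.0)) if read_length else None
    return Prediction(rate=rate, n_mismatches=n, extrapolated=extrapolated)


def holdout_rmse(train_points, test_points) -> float:
    """RMSE of the train-fitted line's predictions on held-out points."""
    test = [(float(x), float(y)) for x, y in test_points]
    if not test:
        raise ValueError("holdout_rmse: empty test set")
    model = fit_linear(train_points)
    err = [model.slope * x + model.intercept - y for x, y in test]
    return float(np.sqrt(np.mean(np.square(err))))


def decide(ref_available: bool, distances: dict | None,
           model: LinearModel | None = None,
           thresholds: DecisionThresholds = DEFAULT_THRESHOLDS,
           ambiguous_fraction: float | None = None,
           read_length: int | None = None) -> Decision:
    """Run the strategy decision flow.

    ``distances`` maps marker names ("ortholog", "16s", "dloop") to
    genetic distances from the candidate pseudo-reference species.  The
    first available marker in the preference order is used.  Boundary
    inclusive: distance == bound still recommends PRA.
    """
    warns = []
    if ambiguous_fraction is not None and ambiguous_fraction > thresholds.ambiguous_warn:
        warns.append(
            f"high ambiguous-base fraction ({ambiguous_fraction:.3f} > "
            f"{thresholds.ambiguous_warn:g}): the observed optimal mismatch "
            "rate may exceed the model prediction"
        )
    if ref_available:
        return Decision(Strategy.REFERENCE_BASED, None,
                        "reference genome available", warns)
    distances = distances or {}
    marker = next((m for m in thresholds.preference if m in distances), None)
    if marker is None:
        raise ValueError(
            "cannot decide: no reference genome and no marker distance"
        )
    d = float(distances[marker])
    bound = thresholds.bound_for(marker)
    if d > bound:
        return Decision(
            Strategy.DE_NOVO, None,
            f"{marker} distance {d:g} exceeds bound {bound:g}",
            warns, marker, d)
    if model is None:
        model = default_model()
    pred = predict_mismatch(model, d, read_length)
    if pred.rate > thresholds.max_mismatch_rate:
        return Decision(
            Strategy.DE_NOVO, None,
            f"predicted optimal mismatch rate {pred.rate:.2f}% exceeds "
            f"bound {thresholds.max_mismatch_rate:g}%",
            warns, marker, d)
    return Decision(
        Strategy.PRA, pred.rate,
        f"{marker} distance {d:g} within bound {bound:g}; predicted "
        f"optimal mismatch rate {pred.rate:.2f}%",
        warns, marker, d)


def load_model_tsv(path_or_text) -> LinearModel:
    """Fit a model from a TSV of (x, optimal_mismatch_rate_percent) rows.

    Lines starting with '#' are comments.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    points = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        points.append((float(fields[0]), float(fields[1])))
    return fit_linear(points)


def default_model() -> LinearModel:
    """The bundled model: a seeded virtual-genome run re-fitted on load."""
    ref = resources.files("pseudoref").joinpath("data/default_model_points.tsv")
    with ref.open() as fh:
        return load_model_tsv(fh)
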