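"""Parameter-combination classification and ROC evaluation.

Three binary comparisons are defined over a labeled cohort of per-(subject,
time point) characteristic-parameter vectors:

* ``detect_24h`` — experimental vs control observations within (0, 24] h;
* ``detect_1h``  — the same within (0, 1] h (early detection);
* ``phase``      — acute (0, 6] h vs chronic (6, 24] h observations within
  the experimental group.

For a chosen subset of the five parameters, each parameter is mapped to
[-1, 1] by dividing by the pooled maximum absolute value over *both*
classes, and the observation's score is the Euclidean norm of the mapped
vector. Single-parameter subsets are scored on the raw parameter value. A
threshold sweep over the scores yields the ROC curve, its trapezoidal AUC,
and a Youden-optimal operating point; all 31 non-empty subsets are ranked.

The user-facing surface is :class:`CombinationModel` /
:class:`CombinationResults`: build the model from a parameter table (or a
cohort dataset), ``fit()`` it, and read the ranked combination table from
``summary()``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import PARAMETER_NAMES, CharacteristicParameters, parameters_to_frame
from .io import CONTROL, EXPERIMENTAL, CohortDataset, TimeWindow, DEFAULT_WINDOWS

__all__ = [
    "COMPARISONS",
    "LabeledObservation",
    "CombinationScore",
    "RocResult",
    "ConfigurationError",
    "DegenerateScoreWarning",
    "build_observations",
    "map_and_score",
    "roc_analysis",
    "evaluate_all_combinations",
    "all_combinations",
    "CombinationModel",
    "CombinationResults",
]

#: Comparison id -> (positive-class selector, negative-class selector),
#: each a (group, window-name) pair.
COMPARISONS = {
    "detect_24h": ((EXPERIMENTAL, "full"), (CONTROL, "full")),
    "detect_1h": ((EXPERIMENTAL, "early"), (CONTROL, "early")),
    "phase": ((EXPERIMENTAL, "acute"), (EXPERIMENTAL, "chronic")),
}


class ConfigurationError(ValueError):
    """A comparison is undefined on the given data (e.g. an empty class)."""


class DegenerateScoreWarning(UserWarning):
    """All scores identical; ROC collapses to chance."""


@dataclass(frozen=True)
class LabeledObservation:
    """One (subject, time point) parameter vector with its binary label
    for a specific comparison (True = positive class)."""

    features: CharacteristicParameters
    label: bool
    comparison_id: str


@dataclass(frozen=True)
class CombinationScore:
    """Euclidean scores of all observations for one parameter subset.

    ``norms`` holds the pooled max-absolute value per parameter actually
    used for the [-1, 1] mapping (empty for single-parameter subsets,
    which are scored raw).
    """

    combination: tuple[str, ...]
    norms: dict[str, float]
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class RocResult:
    """ROC curve summary for one score set.

    ``auc`` is orientation-corrected to >= 0.5 (``flipped`` records whether
    the score direction was inverted; when True, ``thresholds`` apply to
    the *negated* scores). ``sensitivity``/``specificity`` are taken at the
    threshold maximizing Youden's J = sens + spec - 1, ties broken toward
    higher sensitivity.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity_curve: np.ndarray
    specificity_curve: np.ndarray
    optimal_threshold: float
    sensitivity: float
    specificity: float
    flipped: bool

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def window_label(dataset: CohortDataset, comparison_id: str, subject: str, time_h: float):
    """Return True/False/None: positive, negative, or outside the comparison."""
    (pos_group, pos_win), (neg_group, neg_win) = COMPARISONS[comparison_id]
    group = dataset.group_of[subject]
    if group == pos_group and dataset.windows[pos_win].contains(time_h):
        return True
    if group == neg_group and dataset.windows[neg_win].contains(time_h):
        return False
    return None


def build_observations(
    dataset: CohortDataset,
    features: list[CharacteristicParameters],
    comparison_id: str,
) -> list[LabeledObservation]:
    """Label extracted parameter vectors for one comparison.

    Observations are individual (subject, time point) measurements;
    baseline (t0) vectors never enter (windows are open at 0). Raises
    :class:`ConfigurationError` if either class ends up empty.
    """
    if comparison_id not in COMPARISONS:
        raise ConfigurationError(
            f"unknown comparison {comparison_id!r}; expected one of {sorted(COMPARISONS)}"
        )
    obs: list[LabeledObservation] = []
    for p in features:
        lab = window_label(dataset, comparison_id, p.subject_id, p.time_h)
        if lab is not None:
            obs.append(LabeledObservation(features=p, label=lab, comparison_id=comparison_id))
    n_pos = sum(o.label for o in obs)
    n_neg = len(obs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError(
            f"comparison {comparison_id!r}: empty class after windowing "
            f"(positives={n_pos}, negatives={n_neg})"
        )
    return obs


def map_and_score(
    observations: list[LabeledObservation], combination: tuple[str, ...] | list[str]
) -> CombinationScore:
    """Score every observation on a parameter subset.

    Multi-parameter subsets: each parameter is divided by its pooled
    max-absolute value over all observations (both classes), then the
    score is the Euclidean norm of the mapped vector — so each mapped
    value lies in [-1, 1] and scores lie in [0, sqrt(k)]. A parameter
    whose pooled max is 0 contributes 0 (with a warning). Single-parameter
    subsets are scored on the raw value.
    """
    combination = tuple(combination)
    if not combination:
        raise ValueError("combination must be non-empty")
    unknown = set(combination) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)}")
    labels = np.array([o.label for o in observations], dtype=bool)
    mat = np.array(
        [[getattr(o.features, p) for p in combination] for o in observations]
    )
    if len(combination) == 1:
        return CombinationScore(combination, {}, mat[:, 0].copy(), labels)
    norms: dict[str, float] = {}
    mapped = np.zeros_like(mat)
    for k, p in enumerate(combination):
        m = float(np.max(np.abs(mat[:, k])))
        norms[p] = m
        if m == 0.0:
            warnings.warn(
                f"parameter {p!r} is identically zero over all observations; "
                "it contributes 0 to the combination score",
                UserWarning,
                stacklevel=2,
            )
        else:
            mapped[:, k] = mat[:, k] / m
    return CombinationScore(combination, norms, np.sqrt((mapped**2).sum(axis=1)), labels)


def _sweep(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    """Sensitivity/specificity at each threshold with rule score >= t -> positive."""
    pos = scores[labels]
    neg = scores[~labels]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return sens, spec


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Threshold-sweep ROC of a score set.

    Candidate thresholds are midpoints between consecutive distinct sorted
    scores plus +/-inf sentinels; AUC is the trapezoidal area over the
    (FPR, TPR) curve, equal to the tie-aware Mann-Whitney pair statistic.
    The score orientation is chosen so AUC >= 0.5 (``flipped`` records it);
    with a single distinct score the result is chance (AUC 0.5) and a
    :class:`DegenerateScoreWarning` is emitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or not labels.any():
        raise ConfigurationError("both classes must be non-empty")

    distinct = np.unique(scores)
    if distinct.size == 1:
        warnings.warn(
            "all scores identical; ROC is degenerate (AUC 0.5)",
            DegenerateScoreWarning,
            stacklevel=2,
        )

    def curve(s: np.ndarray):
        d = np.unique(s)
        mids = (d[:-1] + d[1:]) / 2.0
        thr = np.concatenate(([-np.inf], mids, [np.inf]))
        sens, spec = _sweep(s, labels, thr)
        # thresholds ascending -> FPR non-increasing; reverse for trapezoid
        fpr = 1.0 - spec
        auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
        return thr, sens, spec, auc

    thr, sens, spec, auc = curve(scores)
    flipped = False
    if auc < 0.5:
        # orientation convention: report the better-than-chance direction;
        # when flipped, thresholds apply to the negated scores
        flipped = True
        thr, sens, spec, auc = curve(-scores)

    j = sens + spec - 1.0
    # Youden maximizer; ties broken toward higher sensitivity
    best = max(range(len(j)), key=lambda k: (j[k], sens[k]))
    return RocResult(
        auc=auc,
        thresholds=thr,
        sensitivity_curve=sens,
        specificity_curve=spec,
        optimal_threshold=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        flipped=flipped,
    )


def all_combinations() -> list[tuple[str, ...]]:
    """The 31 non-empty subsets of the five parameters, grouped by size
    (5 single, 10 double, 10 triple, 5 quadruple, 1 quintuple)."""
    combos: list[tuple[str, ...]] = []
    for k in range(1, 6):
        combos.extend(itertools.combinations(PARAMETER_NAMES, k))
    return combos


def _format_2sig(auc: float) -> str:
    """AUC rounded to two significant digits for display."""
    if auc == 0:
        return "0.0"
    from math import floor, log10

    digits = 1 - floor(log10(abs(auc)))
    rounded = round(auc, digits)
    if abs(rounded) >= 10 ** (2 - digits):  # rounding gained a digit (0.9985 -> 1.0)
        digits -= 1
        rounded = round(auc, digits)
    return f"{rounded:.{max(digits, 0)}f}"


def evaluate_all_combinations(
    observations: list[LabeledObservation],
) -> pd.DataFrame:
    """Rank all 31 parameter subsets by ROC performance.

    Returns a DataFrame with one row per subset: combination, size, AUC at
    full precision, the two-significant-digit display AUC, and the Youden
    operating point's sensitivity and specificity. Rows are grouped by
    combination size.
    """
    rows = []
    for combo in all_combinations():
        cs = map_and_score(observations, combo)
        roc = roc_analysis(cs.scores, cs.labels)
        rows.append(
            {
                "combination": "+".join(combo),
                "size": len(combo),
                "auc": roc.auc,
                "auc_2sig": _format_2sig(roc.auc),
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "threshold": roc.optimal_threshold,
                "flipped": roc.flipped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class CombinationModel:
    """Exhaustive parameter-combination classifier for one comparison.

    Parameters
    ----------
    features : list of CharacteristicParameters
        Per-(subject, time point) parameter vectors from
        :func:`abcpe.extraction.extract_series`.
    dataset : CohortDataset
        Supplies group labels and time-window definitions.
    comparison : str
        ``detect_24h``, ``detect_1h`` or ``phase``.

    Examples
    --------
    >>> model = CombinationModel.from_cohort(cohort, "detect_24h")  # doctest: +SKIP
    >>> res = model.fit()                                           # doctest: +SKIP
    >>> print(res.summary())                                        # doctest: +SKIP
    """

    def __init__(
        self,
        features: list[CharacteristicParameters],
        dataset: CohortDataset,
        comparison: str = "detect_24h",
    ):
        self.features = features
        self.dataset = dataset
        self.comparison = comparison
        self.observations = build_observations(dataset, features, comparison)

    @classmethod
    def from_cohort(cls, dataset: CohortDataset, comparison: str = "detect_24h"):
        """Extract parameters from the raw cohort, then build the model."""
        from .extraction import extract_series

        params, errors = extract_series(dataset)
        if errors:
            warnings.warn(f"{len(errors)} record(s) failed extraction", UserWarning)
        return cls(params, dataset, comparison)

    @property
    def n_positive(self) -> int:
        return sum(o.label for o in self.observations)

    @property
    def n_negative(self) -> int:
        return len(self.observations) - self.n_positive

    def score(self, combination: tuple[str, ...] | list[str]) -> CombinationScore:
        return map_and_score(self.observations, combination)

    def roc(self, combination: tuple[str, ...] | list[str]) -> RocResult:
        cs = self.score(combination)
        return roc_analysis(cs.scores, cs.labels)

    def fit(self) -> "CombinationResults":
        """Evaluate all 31 combinations and return the results object."""
        table = evaluate_all_combinations(self.observations)
        return CombinationResults(model=self, table=table)


@dataclass
class CombinationResults:
    """Fitted combination ranking with summary and plotting helpers."""

    model: CombinationModel
    table: pd.DataFrame
    _roc_cache: dict = field(default_factory=dict, repr=False)

    @property
    def best(self) -> pd.Series:
        """Row of the highest-AUC combination (first on ties)."""
        return self.table.loc[self.table["auc"].idxmax()]

    def auc(self, combination: tuple[str, ...] | list[str]) -> float:
        key = "+".join(combination)
        row = self.table[self.table["combination"] == key]
        if row.empty:
            raise KeyError(f"no combination {key!r}")
        return float(row["auc"].iloc[0])

    def roc(self, combination: tuple[str, ...] | list[str]) -> RocResult:
        key = tuple(combination)
        if key not in self._roc_cache:
            self._roc_cache[key] = self.model.roc(key)
        return self._roc_cache[key]

    def summary(self) -> str:
        """Formatted report: cohort sizes, per-size combination tables,
        and the best-combination line."""
        m = self.model
        lines = [
            f"Parameter-combination ROC evaluation — comparison: {m.comparison}",
            f"Observations: {m.n_positive} positive, {m.n_negative} negative "
            "(one per subject-time point)",
            "",
        ]
        size_names = {1: "Single", 2: "Double", 3: "Triple", 4: "Quadruple", 5: "Quintuple"}
        for size, chunk in self.table.groupby("size"):
            lines.append(f"{size_names[size]} ({len(chunk)} combinations)")
            lines.append(f"{'combination':<28}{'AUC':>8}{'AUC(2sig)':>11}{'sens':>8}{'spec':>8}")
            for _, r in chunk.iterrows():
                lines.append(
                    f"{r['combination']:<28}{r['auc']:>8.4f}{r['auc_2sig']:>11}"
                    f"{r['sensitivity']:>8.3f}{r['specificity']:>8.3f}"
                )
            lines.append("")
        b = self.best
        lines.append(
            f"Best combination: {b['combination']} "
            f"(AUC {b['auc']:.4f}, sensitivity {b['sensitivity']:.1%}, "
            f"specificity {b['specificity']:.1%})"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def plot_roc(self, combination: tuple[str, ...] | list[str], ax=None):
        """Plot the ROC curve of one combination (requires matplotlib)."""
        import matplotlib.pyplot as plt

        roc = self.roc(tuple(combination))
        if ax is None:
            _, ax = plt.subplots()
        fpr = 1.0 - roc.specificity_curve
        order = np.argsort(fpr)
        ax.plot(fpr[order], roc.sensitivity_curve[order], label="+".join(combination))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.model.comparison}: AUC = {roc.auc:.3f}")
        ax.legend()
        return ax
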