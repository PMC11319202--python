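"""Two-stage polygenic scores and their evaluation.

Stage one turns per-coordinate variant effects into per-individual
scores s_ik = sum_j g_ij * beta_jk.  Stage two fits a small linear model
w on the coordinate scores against a disease label and combines them
into y_i = intercept + sum_k s_ik * w_k.  Evaluation covers AUC-ROC,
AUC-PR, Pearson r, prevalence in the top/bottom score percentiles, and
percentile bootstrap confidence intervals with paired significance
between two competing scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import GenotypePanel

__all__ = [
    "CoordinateEffects",
    "DiseaseWeights",
    "coordinate_prs",
    "fit_disease_weights",
    "disease_score",
    "evaluate_scores",
    "paired_bootstrap",
    "subsample_cases",
]

PERCENTILE_CUTS = (0.01, 0.05, 0.10, 0.20)
BOOTSTRAP_REPS = 300


@dataclass
class CoordinateEffects:
    """Per-variant effect sizes for each latent coordinate.

    ``table`` columns: ID, CHR, POS, EFFECT_ALLELE, OTHER_ALLELE, then one
    BETA_<coordinate> column per coordinate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ID", "CHR", "POS", "EFFECT_ALLELE", "OTHER_ALLELE"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"effects table missing columns: {sorted(missing)}")
        if not self.beta_columns:
            raise ValueError("effects table has no BETA_* columns")
        betas = self.table[self.beta_columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(betas)):
            raise ValueError("effect sizes must be finite")

    @property
    def beta_columns(self) -> list:
        return [c for c in self.table.columns if c.startswith("BETA_")]

    @property
    def coordinates(self) -> list:
        return [c[len("BETA_") :] for c in self.beta_columns]

    @classmethod
    def from_scans(cls, scans: Sequence[pd.DataFrame],
                   names: Optional[Sequence[str]] = None) -> "CoordinateEffects":
        """Assemble effects from association-scan summary tables."""
        names = list(names) if names else [
            s.attrs.get("coordinate", f"coord_{i + 1}") for i, s in enumerate(scans)
        ]
        base = scans[0][["ID", "CHR", "POS", "ALT", "REF"]].rename(
            columns={"ALT": "EFFECT_ALLELE", "REF": "OTHER_ALLELE"}
        )
        for name, scan in zip(names, scans):
            if not scan["ID"].equals(scans[0]["ID"]):
                raise ValueError("scans cover different variants")
            base[f"BETA_{name}"] = scan["BETA"].to_numpy()
        return cls(base)


@dataclass
class DiseaseWeights:
    weights: np.ndarray
    intercept: float
    coordinates: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coordinates and len(self.coordinates) != len(self.weights):
            raise ValueError("coordinate names and weights disagree in length")


def coordinate_prs(
    panel: GenotypePanel,
    effects: CoordinateEffects,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Dosage-weighted sums per coordinate: s_ik = sum_j g_ij beta_jk.

    Variants are harmonized by (chromosome, position, alleles): when the
    effect allele equals the panel's ref allele the dosage is flipped to
    2 - g.  Strand-ambiguous (A/T, C/G) variants are kept by default —
    synthetic panels are strand-unambiguous — or dropped with a flag.
    Unharmonizable variants are excluded with a warning count.
    """
    pv = panel.variants.set_index(["chromosome", "position"])
    betas = effects.table[effects.beta_columns].to_numpy(dtype=float)
    n_excluded = 0
    scores = np.zeros((panel.n, len(effects.beta_columns)))
    ambiguous = {frozenset(("A", "T")), frozenset(("C", "G"))}
    for row_i, row in enumerate(effects.table.itertuples(index=False)):
        key = (row.CHR, row.POS)
        if key not in pv.index:
            n_excluded += 1
            continue
        match = pv.loc[key]
        if isinstance(match, pd.DataFrame):
            match = match.iloc[0]
        ea, oa = row.EFFECT_ALLELE, row.OTHER_ALLELE
        if drop_ambiguous and frozenset((ea, oa)) in ambiguous:
            n_excluded += 1
            continue
        j = panel.variants.index[panel.variants["id"] == match["id"]][0]
        g = panel.dosages[:, j]
        if ea == match["alt"] and oa == match["ref"]:
            dose = g
        elif ea == match["ref"] and oa == match["alt"]:
            dose = 2.0 - g
        else:
            n_excluded += 1
            continue
        scores += np.outer(dose, betas[row_i])
    if n_excluded:
        warnings.warn(f"{n_excluded} variants could not be harmonized; excluded")
    return pd.DataFrame(scores, index=list(panel.sample_ids),
                        columns=effects.coordinates)


def subsample_cases(
    labels: pd.Series, n_cases: int, seed: int = 0,
    n_controls: Optional[int] = None,
) -> pd.Index:
    """Random subsample keeping ``n_cases`` cases (all controls by default).

    Emulates label-scarce weight fitting: coordinate scores come from the
    full GWAS, only the final linear combination sees few labels.
    """
    rng = np.random.default_rng(seed)
    cases = labels.index[labels == 1]
    controls = labels.index[labels == 0]
    if n_cases > len(cases):
        raise ValueError(f"requested {n_cases} cases but only {len(cases)} exist")
    keep_cases = rng.choice(cases, size=n_cases, replace=False)
    if n_controls is not None:
        controls = rng.choice(controls, size=n_controls, replace=False)
    return pd.Index(np.concatenate([keep_cases, controls]))


def fit_disease_weights(
    scores: pd.DataFrame,
    labels: pd.Series,
    method: str = "linear",
) -> DiseaseWeights:
    """Fit the stage-two combination weights on the coordinate scores.

    Default is least squares of the (binary or continuous) label on the T
    scores plus intercept; logistic regression is available for binary
    labels behind ``method="logistic"``.
    """
    shared = scores.index.intersection(labels.index)
    if len(shared) < scores.shape[1] + 2:
        raise ValueError("need at least T + 2 labeled individuals")
    S = scores.loc[shared].to_numpy(dtype=float)
    y = labels.loc[shared].to_numpy(dtype=float)
    if method == "linear":
        X = np.column_stack([np.ones(len(S)), S])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return DiseaseWeights(coef[1:], float(coef[0]), list(scores.columns))
    if method == "logistic":
        if len(np.unique(y)) < 2:
            raise ValueError("logistic fit requires both classes present")
        clf = LogisticRegression(penalty=None, max_iter=1000).fit(S, y)
        return DiseaseWeights(clf.coef_[0], float(clf.intercept_[0]),
                              list(scores.columns))
    raise ValueError(f"unknown method {method!r}")


def disease_score(scores: pd.DataFrame, weights: DiseaseWeights) -> pd.Series:
    """Combine coordinate scores: y_i = intercept + sum_k s_ik w_k."""
    if weights.coordinates and list(scores.columns) != list(weights.coordinates):
        raise ValueError("coordinate sets of scores and weights differ")
    if scores.shape[1] != len(weights.weights):
        raise ValueError("weight count does not match score columns")
    y = weights.intercept + scores.to_numpy(dtype=float) @ weights.weights
    return pd.Series(y, index=scores.index, name="disease_score")


def _prevalence_cuts(score: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    n = len(score)
    # strict rank cut by score, ties broken by stable original order
    order_desc = np.lexsort((np.arange(n), -score))
    order_asc = np.lexsort((np.arange(n), score))
    out = {}
    for frac in PERCENTILE_CUTS:
        k = max(1, int(n * frac))
        pct = int(round(frac * 100))
        out[f"prevalence_top_{pct}pct"] = float(labels[order_desc[:k]].mean())
        out[f"prevalence_bottom_{pct}pct"] = float(labels[order_asc[:k]].mean())
    return out


def evaluate_scores(
    score: np.ndarray, labels: np.ndarray, continuous: bool = False
) -> Dict[str, float]:
    """Discrimination and calibration summary of one score.

    Binary labels: AUC-ROC (midrank concordance), AUC-PR (step-integrated
    precision–recall), Pearson r and top/bottom percentile prevalences.
    Continuous labels: Pearson r only.  Single-class binary labels leave
    the AUCs absent.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if score.shape != labels.shape:
        raise ValueError("score and label lengths differ")
    out: Dict[str, float] = {}
    out["pearson_r"] = float(stats.pearsonr(score, labels)[0]) if len(score) > 1 else float("nan")
    if continuous:
        return out
    classes = np.unique(labels)
    if len(classes) < 2:
        return out  # AUCs undefined
    out["auc_roc"] = float(roc_auc_score(labels, score))
    out["auc_pr"] = float(average_precision_score(labels, score))
    out.update(_prevalence_cuts(score, labels))
    return out


def _metric(score, labels, name: str) -> float:
    if name == "auc_roc":
        if len(np.unique(labels)) < 2:
            return float("nan")
        return float(roc_auc_score(labels, score))
    if name == "auc_pr":
        if len(np.unique(labels)) < 2:
            return float("nan")
        return float(average_precision_score(labels, score))
    if name == "pearson_r":
        return float(stats.pearsonr(score, labels)[0])
    raise ValueError(f"unknown metric {name!r}")


def paired_bootstrap(
    score_a: np.ndarray,
    score_b: np.ndarray,
    labels: np.ndarray,
    metric: str = "auc_roc",
    reps: int = BOOTSTRAP_REPS,
    seed: int = 0,
) -> Dict[str, object]:
    """Percentile bootstrap CIs for two scores plus paired significance.

    Individuals are resampled with replacement ``reps`` times; both
    methods see identical resamples (pairing).  The difference is called
    significant when the two-sided 95% percentile interval of
    metric(A) - metric(B) excludes zero.  Degenerate resamples (single
    class) are skipped for both methods alike.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap repetitions")
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores and labels must cover identical individuals")
    rng = np.random.default_rng(seed)
    n = len(y)
    va, vb = [], []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        ma = _metric(a[idx], y[idx], metric)
        mb = _metric(b[idx], y[idx], metric)
        if np.isnan(ma) or np.isnan(mb):
            continue
        va.append(ma)
        vb.append(mb)
    va = np.asarray(va)
    vb = np.asarray(vb)
    diff = va - vb
    lo, hi = np.percentile(diff, [2.5, 97.5])
    point_a = _metric(a, y, metric)
    point_b = _metric(b, y, metric)
    ci_a = tuple(np.percentile(va, [2.5, 97.5]))
    ci_b = tuple(np.percentile(vb, [2.5, 97.5]))
    return {
        "metric": metric,
        "point_a": point_a,
        "point_b": point_b,
        "ci_a": (min(ci_a[0], point_a), max(ci_a[1], point_a)),
        "ci_b": (min(ci_b[0], point_b), max(ci_b[1], point_b)),
        "ci_diff": (float(lo), float(hi)),
        "significant": bool(lo > 0.0 or hi < 0.0),
    }
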