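"""Symptom panel data model, IO, PGSI scoring and paired descriptives.

The central container is :class:`SymptomPanel`: per-person responses to a
set of labelled symptom items (by default the nine PGSI items) at one or
two measurement waves, either on the original ordinal 0-3 scale or
dichotomized to 0/1 ("never" vs "at least sometimes").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PGSI_ITEMS",
    "SymptomPanel",
    "RiskCategory",
    "PairedTestResult",
    "ColumnMap",
    "read_panel",
    "write_panel",
    "score_pgsi",
    "classify_risk",
    "dichotomize",
    "prevalence_table",
    "cronbach_alpha",
    "paired_t",
    "mcnemar",
]

#: The nine PGSI items, numbered as conventionally abbreviated in
#: symptom-network figures.
PGSI_ITEMS = (
    "1. Betting more than one can afford",
    "2. Tolerance",
    "3. Chasing losses",
    "4. Borrowing money",
    "5. Recognizes one has a problem",
    "6. Health problems",
    "7. Criticized by others",
    "8. Financial problems",
    "9. Feelings of guilt",
)


class RiskCategory(Enum):
    """PGSI gambling-risk category from the total score (0-27)."""

    NON_PROBLEMATIC = "non_problematic"   # 0
    LOW_RISK = "low_risk"                 # 1-2
    MODERATE_RISK = "moderate_risk"       # 3-7
    SEVERE = "severe"                     # >= 8


@dataclass(frozen=True)
class ColumnMap:
    """How panel item responses are laid out in a wide CSV.

    Column names follow ``template.format(item=i, wave=w)``, e.g. the
    default template ``"pg{item}_w{wave}"`` expects ``pg1_w1 .. pg9_w2``.
    """

    template: str = "pg{item}_w{wave}"
    n_items: int = 9
    waves: tuple = (1, 2)
    id_column: str | None = "id"
    covariates: tuple = ("sex", "age")

    def column(self, item: int, wave: int) -> str:
        return self.template.format(item=item, wave=wave)


@dataclass
class SymptomPanel:
    """Per-person symptom responses at one or more waves.

    Attributes
    ----------
    responses : int array of shape (n_persons, n_items, n_waves);
        entries in {0,1,2,3} for the ordinal scale or {0,1} for binary.
        Missing values are coded -1 and flagged in ``complete``.
    scale : "ordinal0to3" or "binary".
    """

    responses: np.ndarray
    scale: str = "ordinal0to3"
    item_labels: tuple = PGSI_ITEMS
    wave_labels: tuple = ("Wave 1", "Wave 2")
    covariates: pd.DataFrame | None = None
    complete: np.ndarray = field(init=False)

    def __post_init__(self):
        r = np.asarray(self.responses)
        if r.ndim == 2:
            r = r[:, :, None]
        if r.ndim != 3:
            raise ValueError("responses must be (persons, items[, waves])")
        if r.shape[1] < 2:
            raise ValueError("a symptom panel needs at least 2 items")
        self.responses = r.astype(np.int64)
        hi = 3 if self.scale == "ordinal0to3" else 1
        valid = ((self.responses >= 0) & (self.responses <= hi)) | (self.responses == -1)
        if not valid.all():
            bad = np.unique(self.responses[~valid])
            raise ValueError(
                f"out-of-range responses {bad.tolist()} for scale {self.scale!r}"
            )
        self.item_labels = tuple(self.item_labels)[: r.shape[1]]
        if len(self.item_labels) != r.shape[1]:
            self.item_labels = tuple(f"item{i+1}" for i in range(r.shape[1]))
        self.wave_labels = tuple(self.wave_labels)[: r.shape[2]]
        if len(self.wave_labels) != r.shape[2]:
            self.wave_labels = tuple(f"Wave {w+1}" for w in range(r.shape[2]))
        self.complete = ~np.any(self.responses == -1, axis=(1, 2))

    # -- basic geometry -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_waves(self) -> int:
        return self.responses.shape[2]

    def wave(self, w: int) -> np.ndarray:
        """Person x item matrix of a single wave (0-based index)."""
        return self.responses[:, :, w]

    def complete_cases(self) -> "SymptomPanel":
        """Drop persons with any missing response (analysis stages
        require complete data; the number dropped is logged)."""
        if self.complete.all():
            return self
        n_drop = int((~self.complete).sum())
        logger.info("dropping %d of %d persons with incomplete responses",
                    n_drop, self.n_persons)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[self.complete].reset_index(drop=True)
        return SymptomPanel(self.responses[self.complete], self.scale,
                            self.item_labels, self.wave_labels, cov)

    def require_complete(self, what: str = "analysis") -> None:
        if not self.complete.all():
            raise ValueError(
                f"{what} requires complete cases; call .complete_cases() "
                f"first ({int((~self.complete).sum())} incomplete rows)"
            )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, column_map: ColumnMap | None = None) -> SymptomPanel:
    """Read a wide one-row-per-person CSV into a :class:`SymptomPanel`.

    Missing item responses become explicit (-1) and are flagged; values
    outside the declared scale raise.  Duplicate person IDs raise.
    """
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path)
    if cmap.id_column and cmap.id_column in df.columns:
        if df[cmap.id_column].duplicated().any():
            dup = df[cmap.id_column][df[cmap.id_column].duplicated()].tolist()
            raise ValueError(f"duplicate person IDs: {dup[:5]}")
    cols = [[cmap.column(i + 1, w) for w in cmap.waves] for i in range(cmap.n_items)]
    missing_cols = [c for row in cols for c in row if c not in df.columns]
    if missing_cols:
        raise ValueError(f"expected item columns not found: {missing_cols[:6]}")
    n = len(df)
    resp = np.full((n, cmap.n_items, len(cmap.waves)), -1, dtype=np.int64)
    for i in range(cmap.n_items):
        for wi, w in enumerate(cmap.waves):
            col = pd.to_numeric(df[cmap.column(i + 1, w)], errors="coerce")
            vals = col.to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            resp[ok, i, wi] = vals[ok].astype(np.int64)
    values = resp[resp >= 0]
    scale = "binary" if values.size and values.max() <= 1 else "ordinal0to3"
    if values.size and values.max() > 3:
        raise ValueError(f"item responses above 3 found (max={values.max()})")
    covs = [c for c in (cmap.covariates or ()) if c in df.columns]
    cov = df[covs].copy() if covs else None
    labels = PGSI_ITEMS if cmap.n_items == 9 else tuple(
        f"item{i+1}" for i in range(cmap.n_items))
    panel = SymptomPanel(resp, scale, labels,
                         tuple(f"Wave {w}" for w in cmap.waves), cov)
    if not panel.complete.all():
        logger.warning("%d persons have missing item responses",
                       int((~panel.complete).sum()))
    return panel


def write_panel(panel: SymptomPanel, path: str | Path,
                column_map: ColumnMap | None = None) -> None:
    """Write a panel to the wide CSV layout read by :func:`read_panel`."""
    cmap = column_map or ColumnMap(n_items=panel.n_items,
                                   waves=tuple(range(1, panel.n_waves + 1)))
    data = {}
    if cmap.id_column:
        data[cmap.id_column] = np.arange(1, panel.n_persons + 1)
    for i in range(panel.n_items):
        for wi, w in enumerate(cmap.waves):
            col = panel.responses[:, i, wi].astype(object)
            data[cmap.column(i + 1, w)] = [v if v >= 0 else "" for v in col]
    df = pd.DataFrame(data)
    if panel.covariates is not None:
        for c in panel.covariates.columns:
            df[c] = panel.covariates[c].to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

def score_pgsi(responses, scale: str = "ordinal0to3") -> np.ndarray:
    """PGSI total score: the sum of the nine ordinal (0-3) item values.

    Defined on the ordinal scale only; totals range 0-27.
    Accepts a single response vector or a (persons x items) matrix.
    """
    if scale != "ordinal0to3":
        raise ValueError("PGSI total score is defined on ordinal 0-3 items, "
                         "not on dichotomized responses")
    r = np.asarray(responses)
    if np.any(r < 0) or np.any(r > 3):
        raise ValueError("ordinal item values must lie in {0,1,2,3}")
    return r.sum(axis=-1)


_RISK_CUTS = ((0, 0, RiskCategory.NON_PROBLEMATIC),
              (1, 2, RiskCategory.LOW_RISK),
              (3, 7, RiskCategory.MODERATE_RISK),
              (8, 27, RiskCategory.SEVERE))


def classify_risk(total) -> RiskCategory | np.ndarray:
    """Map a PGSI total (0-27) to its gambling-risk category.

    Cut points: 0 -> non-problematic, 1-2 -> low risk, 3-7 -> moderate
    risk, 8+ -> severe problem gambling.
    """
    t = np.asarray(total)
    if np.any(t < 0) or np.any(t > 27):
        raise ValueError("PGSI totals must lie in 0..27")
    def one(v):
        for lo, hi, cat in _RISK_CUTS:
            if lo <= v <= hi:
                return cat
        raise AssertionError  # unreachable: cuts cover 0..27
    if t.ndim == 0:
        return one(int(t))
    return np.array([one(int(v)) for v in t.ravel()], dtype=object).reshape(t.shape)


def dichotomize(panel: SymptomPanel) -> SymptomPanel:
    """Dichotomize ordinal responses: 0 stays 0 ("never"), 1-3 become 1
    ("at least sometimes").  Idempotent; an already-binary panel passes
    through unchanged with a log notice."""
    if panel.scale == "binary":
        logger.info("panel already binary; dichotomize is a no-op")
        return panel
    resp = np.where(panel.responses == -1, -1,
                    (panel.responses >= 1).astype(np.int64))
    return SymptomPanel(resp, "binary", panel.item_labels,
                        panel.wave_labels, panel.covariates)


# ---------------------------------------------------------------------------
# Descriptive tables and statistics
# ---------------------------------------------------------------------------

def prevalence_table(panel: SymptomPanel, group_by: str | None = None) -> pd.DataFrame:
    """Per-symptom endorsement rates and (for ordinal panels) risk-category
    proportions, per wave and optionally per covariate group.

    Percentages are ``100 * count / group size``; counts are exact and
    percentages are reported at full precision (round for display).
    """
    binary = panel if panel.scale == "binary" else dichotomize(panel)
    binary.require_complete("prevalence table")
    groups = {"Total": np.ones(panel.n_persons, dtype=bool)}
    if group_by is not None:
        if panel.covariates is None or group_by not in panel.covariates.columns:
            raise ValueError(f"unknown grouping covariate {group_by!r}")
        for level in pd.unique(panel.covariates[group_by]):
            mask = (panel.covariates[group_by] == level).to_numpy()
            if mask.sum() == 0:
                raise ValueError(f"empty group {level!r}")
            groups[str(level)] = mask
    rows = []
    for gname, mask in groups.items():
        gn = int(mask.sum())
        if gn == 0:
            raise ValueError(f"empty group {gname!r}")
        for w in range(panel.n_waves):
            counts = binary.responses[mask, :, w].sum(axis=0)
            for i, label in enumerate(panel.item_labels):
                rows.append({
                    "group": gname, "wave": panel.wave_labels[w],
                    "measure": label, "count": int(counts[i]),
                    "group_size": gn,
                    "percent": 100.0 * counts[i] / gn,
                })
            if panel.scale == "ordinal0to3":
                totals = score_pgsi(panel.responses[mask, :, w])
                cats = classify_risk(totals)
                for cat in RiskCategory:
                    c = int(np.sum(cats == cat))
                    rows.append({
                        "group": gname, "wave": panel.wave_labels[w],
                        "measure": f"risk:{cat.value}", "count": c,
                        "group_size": gn, "percent": 100.0 * c / gn,
                    })
    return pd.DataFrame(rows)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / variance
    of the total score), with sample (n-1) variances."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a persons x items matrix with >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 persons")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class PairedTestResult:
    """Result of a paired two-wave comparison (t test or McNemar)."""

    statistic: float
    df: int
    p_value: float
    effect_size: float
    effect_size_label: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")


def paired_t(x1, x2) -> PairedTestResult:
    """Dependent-samples t test of wave-2 minus wave-1 scores.

    Reports t, df = n-1, the two-sided p, the Pearson correlation
    between waves, and an effect size d = mean difference /
    sqrt((SD1^2 + SD2^2)/2) — labelled explicitly, with the raw means
    and SDs included so any other d convention can be recomputed.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length vectors")
    n = x1.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x2 - x1
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        if np.all(d == 0):
            # identical waves: no change, t = 0 by convention
            r = np.nan if (x1.std() == 0) else 1.0
            return PairedTestResult(0.0, n - 1, 1.0, 0.0,
                                    "mean_diff / pooled_sd",
                                    {"mean_diff": 0.0, "r": r,
                                     "sd1": x1.std(ddof=1), "sd2": x2.std(ddof=1),
                                     "mean1": x1.mean(), "mean2": x2.mean()})
        raise ValueError("zero variance of differences")
    t = d.mean() / (sd_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    sd1, sd2 = x1.std(ddof=1), x2.std(ddof=1)
    pooled = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    eff = d.mean() / pooled if pooled > 0 else np.nan
    if sd1 > 0 and sd2 > 0:
        r = float(np.corrcoef(x1, x2)[0, 1])
        r_p = 2.0 * stats.t.sf(abs(r) * np.sqrt((n - 2) / max(1e-300, 1 - r**2)), n - 2)
    else:
        r, r_p = np.nan, np.nan
    return PairedTestResult(float(t), n - 1, float(p), float(eff),
                            "mean_diff / pooled_sd",
                            {"mean_diff": float(d.mean()), "r": r, "r_p": r_p,
                             "sd1": float(sd1), "sd2": float(sd2),
                             "mean1": float(x1.mean()), "mean2": float(x2.mean())})


def mcnemar(b1, b2) -> PairedTestResult:
    """McNemar test of paired binary outcomes across two waves.

    With discordant counts b (0 -> 1) and c (1 -> 0): the standard
    chi-square statistic is (b-c)^2/(b+c) on 1 df (no continuity
    correction), and the exact two-sided binomial p is
    2 * P(Binom(b+c, 1/2) <= min(b, c)), capped at 1.  The effect size
    reported is Cohen's g = b/(b+c) - 1/2.
    """
    b1 = np.asarray(b1).astype(int)
    b2 = np.asarray(b2).astype(int)
    if b1.shape != b2.shape or b1.ndim != 1:
        raise ValueError("paired binary vectors required")
    if np.any((b1 < 0) | (b1 > 1) | (b2 < 0) | (b2 > 1)):
        raise ValueError("inputs must be 0/1")
    b = int(np.sum((b1 == 0) & (b2 == 1)))
    c = int(np.sum((b1 == 1) & (b2 == 0)))
    if b + c == 0:
        logger.warning("no discordant pairs; McNemar chi-square undefined")
        return PairedTestResult(np.nan, 1, np.nan, 0.0, "cohens_g",
                                {"b": b, "c": c, "p_binomial": 1.0})
    chi2 = (b - c) ** 2 / (b + c)
    p_std = float(stats.chi2.sf(chi2, 1))
    p_bin = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))
    g = b / (b + c) - 0.5
    return PairedTestResult(float(chi2), 1, p_std, float(g), "cohens_g",
                            {"b": b, "c": c, "p_binomial": p_bin})
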