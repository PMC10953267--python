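"""Panel-data ingestion, scale scoring, descriptives, and covariate residualization.

The data model is a two-wave dyadic panel: mothers report five parenting
practices (warmth, monitoring, hostility, inductive reasoning, harshness) and
adolescents report four mental-health problems (anxiety, depression,
aggression, conduct problems) on multi-item Likert scales, at two measurement
occasions 18 months apart, alongside demographic covariates.

This module turns a wide CSV (one row per dyad, item columns suffixed by
wave) into scored scale variables, computes per-scale descriptives
(skewness, excess kurtosis, Cronbach's alpha), applies the reliability
exclusion rule (a scale is dropped only when alpha falls below threshold at
*both* waves), and residualizes scale scores on covariates so that the
downstream networks reflect covariate-adjusted associations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import round_half_away
from .errors import ConfigurationError, DataError, ReliabilityError

logger = logging.getLogger(__name__)

WAVES = ("T1", "T2")
DEFAULT_WAVE_SUFFIXES = {"T1": "_t1", "T2": "_t2"}
DEFAULT_COVARIATES = ("gender", "age", "maternal_education", "income_band")

__all__ = [
    "ScaleDefinition",
    "PanelDataset",
    "CovariateResidualizer",
    "read_panel",
    "score_scales",
    "cronbach_alpha",
    "descriptives",
    "drop_unreliable",
    "cohort_summary",
    "residualize",
    "reverse_key",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item Likert scale and how to score it.

    Parameters
    ----------
    name : scale label, e.g. ``"warmth"``.
    construct : ``"parenting"`` or ``"mental_health"``.
    item_ids : base item column names (wave suffix added by the reader).
    reverse_keyed : subset of item_ids scored as ``lo + hi - x``.
    response_range : inclusive integer response bounds ``(lo, hi)``.
    """

    name: str
    construct: str
    item_ids: tuple[str, ...]
    reverse_keyed: tuple[str, ...] = ()
    response_range: tuple[int, int] = (1, 5)

    def __post_init__(self):
        if self.construct not in ("parenting", "mental_health"):
            raise ConfigurationError(
                f"scale {self.name!r}: construct must be 'parenting' or "
                f"'mental_health', got {self.construct!r}"
            )
        if len(self.item_ids) == 0:
            raise ConfigurationError(f"scale {self.name!r}: item_ids is empty")
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reverse_keyed", tuple(self.reverse_keyed))
        extra = set(self.reverse_keyed) - set(self.item_ids)
        if extra:
            raise ConfigurationError(
                f"scale {self.name!r}: reverse_keyed items {sorted(extra)} not in item_ids"
            )
        lo, hi = self.response_range
        if not lo < hi:
            raise ConfigurationError(
                f"scale {self.name!r}: response_range must satisfy lo < hi, got {self.response_range}"
            )


@dataclass
class PanelDataset:
    """Two-wave item responses, scale scores, and covariates, row-aligned by participant.

    ``items[wave]`` and ``scores[wave]`` are participant-indexed DataFrames;
    ``covariates`` shares the same index.  ``n_warnings`` counts responses
    coerced to missing on ingestion (unparseable or out of range).
    """

    items: dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    scale_defs: list[ScaleDefinition]
    scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_warnings: int = 0

    @property
    def participants(self) -> pd.Index:
        return self.items[WAVES[0]].index

    @property
    def n(self) -> int:
        return len(self.participants)

    def scale(self, name: str) -> ScaleDefinition:
        for sd in self.scale_defs:
            if sd.name == name:
                return sd
        raise KeyError(name)

    def item_matrix(self, scale_name: str, wave: str) -> pd.DataFrame:
        """Item responses for one scale at one wave (keyed direction NOT applied)."""
        sd = self.scale(scale_name)
        return self.items[wave][list(sd.item_ids)]


def reverse_key(items: pd.DataFrame, scale: ScaleDefinition) -> pd.DataFrame:
    """Apply reverse-keying: ``x -> lo + hi - x`` on the scale's reverse-keyed items.

    An involution: applying it twice restores the input exactly.
    """
    lo, hi = scale.response_range
    out = items.copy()
    for col in scale.reverse_keyed:
        if col in out.columns:
            out[col] = lo + hi - out[col]
    return out


def read_panel(
    path,
    scale_defs: list[ScaleDefinition],
    wave_suffixes: dict[str, str] | None = None,
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES,
    id_column: str = "participant_id",
) -> PanelDataset:
    """Read a wide-format panel CSV/TSV into a validated :class:`PanelDataset`.

    One row per dyad; item columns are ``<item_id><suffix>`` with per-wave
    suffixes (default ``_t1`` / ``_t2``).  Unparseable or out-of-range
    responses become missing and are counted in ``n_warnings``; duplicate
    participant rows are a hard error.
    """
    wave_suffixes = dict(wave_suffixes or DEFAULT_WAVE_SUFFIXES)
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep)

    if id_column not in raw.columns:
        raise ConfigurationError(f"missing mandatory id column {id_column!r}")
    dup = raw[id_column][raw[id_column].duplicated()]
    if len(dup):
        raise DataError(
            f"duplicate rows for participant(s) {sorted(set(dup.tolist()))}: "
            "at most one record per (participant, wave) is allowed"
        )
    raw = raw.set_index(id_column)

    missing_cols = []
    for sd in scale_defs:
        for wave, suf in wave_suffixes.items():
            for item in sd.item_ids:
                if f"{item}{suf}" not in raw.columns:
                    missing_cols.append(f"{item}{suf}")
    for cov in covariate_columns:
        if cov not in raw.columns:
            missing_cols.append(cov)
    if missing_cols:
        raise ConfigurationError(f"missing mandatory columns: {missing_cols}")

    n_warnings = 0
    items: dict[str, pd.DataFrame] = {}
    for wave, suf in wave_suffixes.items():
        cols = {}
        for sd in scale_defs:
            lo, hi = sd.response_range
            for item in sd.item_ids:
                col = pd.to_numeric(raw[f"{item}{suf}"], errors="coerce")
                bad_parse = col.isna() & raw[f"{item}{suf}"].notna()
                out_of_range = col.notna() & ((col < lo) | (col > hi))
                n_warnings += int(bad_parse.sum() + out_of_range.sum())
                col[out_of_range] = np.nan
                cols[item] = col
        items[wave] = pd.DataFrame(cols, index=raw.index)

    covariates = raw[list(covariate_columns)].apply(pd.to_numeric, errors="coerce")
    if n_warnings:
        logger.warning("read_panel: %d responses coerced to missing", n_warnings)
    return PanelDataset(
        items=items,
        covariates=covariates,
        scale_defs=list(scale_defs),
        n_warnings=n_warnings,
    )


def score_scales(
    data: PanelDataset,
    scale_defs: list[ScaleDefinition] | None = None,
    method: str = "mean",
    min_answered: float = 0.75,
) -> PanelDataset:
    """Populate scale scores: mean (or sum) of keyed items per scale and wave.

    A score is computed from the available items when at least
    ``min_answered`` of the scale's items were answered, otherwise missing.
    """
    scale_defs = scale_defs or data.scale_defs
    if method not in ("mean", "sum"):
        raise ConfigurationError(f"unknown scoring method {method!r}")
    for wave, frame in data.items.items():
        cols = {}
        for sd in scale_defs:
            absent = [i for i in sd.item_ids if i not in frame.columns]
            if absent:
                raise ConfigurationError(
                    f"scale {sd.name!r} references absent item column(s) {absent}"
                )
            keyed = reverse_key(frame[list(sd.item_ids)], sd)
            answered = keyed.notna().sum(axis=1)
            score = keyed.mean(axis=1) if method == "mean" else keyed.sum(axis=1, min_count=1)
            score[answered < min_answered * len(sd.item_ids)] = np.nan
            cols[sd.name] = score
        data.scores[wave] = pd.DataFrame(cols, index=frame.index)
    return data


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum var_i / var_total)``.

    Internal-consistency reliability of a multi-item scale.  Complete rows
    only; sample variances use denominator ``n - 1``.
    """
    x = np.asarray(pd.DataFrame(item_matrix).dropna(), dtype=float)
    n, k = x.shape
    if k < 2:
        raise ConfigurationError(f"alpha requires at least 2 items, got {k}")
    if n < 3:
        raise DataError(f"alpha requires at least 3 complete rows, got {n}")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ReliabilityError("zero total variance: reliability undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sd (n-1), adjusted Fisher-Pearson skewness, excess kurtosis."""
    v = values[~np.isnan(values)]
    if len(v) < 3:
        return (np.nan, np.nan, np.nan, np.nan)
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return (float(np.mean(v)), 0.0, np.nan, np.nan)
    skew = float(stats.skew(v, bias=False))
    kurt = float(stats.kurtosis(v, fisher=True, bias=False))
    return (float(np.mean(v)), sd, skew, kurt)


def descriptives(data: PanelDataset) -> pd.DataFrame:
    """Per (scale, wave): mean, sd, skewness, excess kurtosis, Cronbach's alpha.

    Skewness is the adjusted Fisher-Pearson coefficient and kurtosis is
    small-sample-corrected excess kurtosis — the conventions of common
    commercial statistics software, recorded here so runs are self-describing.
    """
    if not data.scores:
        raise ConfigurationError("scores not populated; call score_scales first")
    rows = []
    for sd_def in data.scale_defs:
        for wave in data.scores:
            mean, sd, skew, kurt = _moments(data.scores[wave][sd_def.name].to_numpy(float))
            try:
                keyed = reverse_key(data.item_matrix(sd_def.name, wave), sd_def)
                alpha = cronbach_alpha(keyed)
            except (ReliabilityError, DataError, ConfigurationError):
                alpha = np.nan
            rows.append(
                {"scale": sd_def.name, "wave": wave, "mean": mean, "sd": sd,
                 "skewness": skew, "kurtosis": kurt, "alpha": alpha}
            )
    return pd.DataFrame(rows).set_index(["scale", "wave"])


def drop_unreliable(descr: pd.DataFrame, threshold: float = 0.60) -> list[str]:
    """Scales retained after the reliability rule.

    A scale is excluded only when alpha < threshold at BOTH waves (a scale
    that clears the bar at either occasion stays in the analysis).
    """
    retained = []
    for scale in descr.index.get_level_values("scale").unique():
        alphas = descr.loc[scale]["alpha"]
        if alphas.isna().any():
            raise ConfigurationError(f"alpha unavailable at both waves for scale {scale!r}")
        if not (alphas < threshold).all():
            retained.append(scale)
        else:
            logger.info("scale %r dropped: alpha %s below %.2f at both waves",
                        scale, alphas.round(2).tolist(), threshold)
    return retained


def cohort_summary(n_t1: int, n_t2: int) -> dict:
    """Attrition report: percent of the T1 cohort lost by T2, to 1 decimal."""
    if not 0 < n_t2 <= n_t1:
        raise DataError(f"need 0 < n_t2 <= n_t1, got n_t1={n_t1}, n_t2={n_t2}")
    pct = round_half_away(100.0 * (n_t1 - n_t2) / n_t1, 1)
    return {"n_t1": int(n_t1), "n_t2": int(n_t2), "attrition_pct": pct}


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Replace score columns with their OLS residuals on encoded covariates.

    Each score column is regressed on an intercept plus the encoded
    covariates (binary indicator for gender; integer ordinal codes for
    education and income bands; age as-is); the transform returns the
    residuals, which are mean-zero and empirically uncorrelated with every
    covariate column.  Degenerate (constant or collinear) covariate columns
    are dropped with a warning, never silently.

    Parameters
    ----------
    covariate_columns : columns of the input frame treated as covariates;
        every other numeric column is treated as a score to residualize.

    Attributes
    ----------
    coef_ : (n_design, n_scores) OLS coefficients.
    design_columns_ : covariate columns retained in the design.
    dropped_columns_ : degenerate covariate columns excluded from the design.
    n_rows_used_ : rows remaining after listwise deletion.
    """

    def __init__(self, covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES):
        self.covariate_columns = covariate_columns

    def _split(self, X: pd.DataFrame):
        cov_cols = [c for c in self.covariate_columns if c in X.columns]
        if len(cov_cols) != len(self.covariate_columns):
            missing = set(self.covariate_columns) - set(cov_cols)
            raise ConfigurationError(f"covariate columns missing from input: {sorted(missing)}")
        score_cols = [c for c in X.columns if c not in cov_cols]
        complete = X[score_cols + cov_cols].dropna()
        return complete[score_cols], complete[cov_cols]

    def fit(self, X: pd.DataFrame, y=None):
        scores, cov = self._split(X)
        n_required = len(cov.columns) + 2
        if len(scores) < n_required:
            raise DataError(
                f"need at least {n_required} complete rows, have {len(scores)}"
            )
        design = cov.astype(float)
        kept, dropped = [], []
        cols = [np.ones(len(design))]
        for c in design.columns:
            candidate = np.column_stack(cols + [design[c].to_numpy()])
            if np.linalg.matrix_rank(candidate) > len(cols):
                cols.append(design[c].to_numpy())
                kept.append(c)
            else:
                dropped.append(c)
        if dropped:
            warnings.warn(
                f"degenerate covariate column(s) dropped from design: {dropped}",
                stacklevel=2,
            )
        D = np.column_stack(cols)
        Y = scores.to_numpy(float)
        self.coef_, *_ = np.linalg.lstsq(D, Y, rcond=None)
        self.design_columns_ = kept
        self.dropped_columns_ = dropped
        self.score_columns_ = list(scores.columns)
        self.n_rows_used_ = len(scores)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scores, cov = self._split(X)
        D = np.column_stack(
            [np.ones(len(cov))] + [cov[c].to_numpy(float) for c in self.design_columns_]
        )
        resid = scores[self.score_columns_].to_numpy(float) - D @ self.coef_
        return pd.DataFrame(resid, index=scores.index, columns=self.score_columns_)


def residualize(scores: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS-residualize every score column on the covariates (listwise-complete rows).

    Thin wrapper over :class:`CovariateResidualizer`.
    """
    X = pd.concat([scores, covariates], axis=1)
    res = CovariateResidualizer(covariate_columns=tuple(covariates.columns))
    return res.fit(X).transform(X)
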