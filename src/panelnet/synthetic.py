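"""Two-wave panel simulator with known ground truth.

Emulates a mother-adolescent dyadic panel: nine scale variables (five
maternal parenting practices, four adolescent mental-health problems)
observed at two waves 18 months apart on n dyads, with demographic
covariates and multi-item Likert measurement.

The generating model is explicit so every pipeline stage is testable:

* T1 scale scores are multivariate normal with the covariance implied by a
  known sparse partial-correlation matrix (within-construct positive blocks,
  a weak negative monitoring-conduct bridge);
* T2 scores follow a stable VAR(1) step ``T2 = T1 B + innovation`` whose
  transition matrix has autoregressive paths of 0.5 on the diagonal and a
  handful of cross-lagged edges (strongest: hostility -> depression 0.23,
  harshness -> hostility 0.20, anxiety -> depression 0.19);
* covariates (adolescent gender and age, maternal education, income band)
  shift scores additively, so covariate residualization is consequential;
* each scale's items follow a one-factor equi-correlation model calibrated
  by the Spearman-Brown relation to hit a target Cronbach's alpha, then are
  discretized to Likert categories by equiprobable normal thresholds (a
  skewed-threshold option mimics heavily skewed scales such as conduct
  problems).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .clpn import TemporalNetwork
from .errors import ConfigurationError
from .ggm import ContemporaneousNetwork, precision_to_partial
from .panel_io import PanelDataset, ScaleDefinition, reverse_key

__all__ = [
    "SimulationSpec",
    "default_spec",
    "default_scale_definitions",
    "simulate_panel",
    "simulate_scores",
    "true_networks",
    "true_centralities",
    "write_panel_csv",
    "spec_to_yaml",
    "spec_from_yaml",
]

NODE_ORDER = (
    "warmth", "monitoring", "inductive_reasoning", "hostility", "harshness",
    "anxiety", "depression", "aggression", "conduct_problems",
)
CONSTRUCTS = {
    "warmth": "parenting", "monitoring": "parenting",
    "inductive_reasoning": "parenting", "hostility": "parenting",
    "harshness": "parenting",
    "anxiety": "mental_health", "depression": "mental_health",
    "aggression": "mental_health", "conduct_problems": "mental_health",
}

# ordinal covariate distributions: education / income bands (4 levels each)
_EDU_PROBS = (0.05, 0.60, 0.30, 0.05)
_INCOME_PROBS = (0.22, 0.50, 0.16, 0.12)


@dataclass
class SimulationSpec:
    """Ground-truth generating model for a two-wave panel."""

    nodes: tuple = NODE_ORDER
    construct_partition: dict = field(default_factory=lambda: dict(CONSTRUCTS))
    true_partial: np.ndarray | None = None   # (p, p) sparse partial correlations
    B: np.ndarray | None = None              # (p, p) transition matrix, diag = AR
    innovation_sd: np.ndarray | None = None  # per-node T2 innovation scale
    covariate_effects: dict = field(default_factory=dict)  # (covariate, node) -> slope
    items_per_scale: dict = field(default_factory=dict)
    target_alpha: dict = field(default_factory=dict)
    likert_levels: int | str = 5             # int >= 2, or "continuous"
    skewed_thresholds: tuple = ()            # scales discretized with skewed cuts
    n: int = 591
    seed: int = 0

    @property
    def p(self) -> int:
        return len(self.nodes)

    def precision(self) -> np.ndarray:
        """Precision matrix implied by the partial correlations (unit diagonal)."""
        theta = -np.asarray(self.true_partial, float).copy()
        np.fill_diagonal(theta, 1.0)
        return theta

    def alphas_for(self, node: str) -> tuple[float, float]:
        """Target reliability at (T1, T2); a scalar target applies to both waves."""
        a = self.target_alpha.get(node)
        if a is None:
            return ()
        return (float(a), float(a)) if np.isscalar(a) else tuple(float(x) for x in a)

    def sigma(self) -> np.ndarray:
        """Implied T1 covariance, rescaled to a correlation matrix."""
        cov = np.linalg.inv(self.precision())
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def validate(self) -> "SimulationSpec":
        p = self.p
        for name, mat in (("true_partial", self.true_partial), ("B", self.B)):
            if mat is None or np.asarray(mat).shape != (p, p):
                raise ConfigurationError(f"{name} must be a {p}x{p} matrix")
        tp = np.asarray(self.true_partial, float)
        if not np.allclose(tp, tp.T, atol=1e-12):
            raise ConfigurationError("true_partial must be symmetric")
        eig = np.linalg.eigvalsh(self.precision())
        if eig.min() <= 1e-10:
            raise ConfigurationError("implied precision matrix is not positive definite")
        rho = np.max(np.abs(np.linalg.eigvals(np.asarray(self.B, float))))
        if rho >= 1:
            raise ConfigurationError(f"transition matrix unstable: spectral radius {rho:.3f} >= 1")
        if self.likert_levels != "continuous" and int(self.likert_levels) < 2:
            raise ConfigurationError("likert_levels must be >= 2 or 'continuous'")
        for node in self.nodes:
            k = self.items_per_scale.get(node, 0)
            for a in self.alphas_for(node):
                rbar = a / (k - a * (k - 1))
                if not 0 < rbar < 1:
                    raise ConfigurationError(
                        f"target alpha {a} unachievable with {k} items for {node!r}"
                    )
        if self.innovation_sd is not None and np.any(np.asarray(self.innovation_sd) <= 0):
            raise ConfigurationError("innovation_sd must be positive")
        return self


def _default_partial() -> np.ndarray:
    p = len(NODE_ORDER)
    idx = {n: i for i, n in enumerate(NODE_ORDER)}
    tp = np.zeros((p, p))
    edges = {
        # positive-parenting block
        ("warmth", "inductive_reasoning"): 0.45,
        ("warmth", "monitoring"): 0.30,
        ("monitoring", "inductive_reasoning"): 0.12,
        # negative-parenting block
        ("hostility", "harshness"): 0.45,
        # within mental health
        ("anxiety", "depression"): 0.50,
        ("aggression", "conduct_problems"): 0.55,
        ("anxiety", "aggression"): 0.16,
        ("depression", "aggression"): 0.09,
        # cross-construct bridges (weak, negative)
        ("monitoring", "conduct_problems"): -0.10,
        ("warmth", "hostility"): -0.08,
        ("warmth", "anxiety"): -0.04,
        ("inductive_reasoning", "harshness"): -0.06,
    }
    for (a, b), w in edges.items():
        tp[idx[a], idx[b]] = tp[idx[b], idx[a]] = w
    return tp


def _default_transition() -> np.ndarray:
    p = len(NODE_ORDER)
    idx = {n: i for i, n in enumerate(NODE_ORDER)}
    B = np.eye(p) * 0.5
    edges = {
        # within-construct cross-lagged paths
        ("harshness", "hostility"): 0.20,
        ("anxiety", "depression"): 0.19,
        ("warmth", "inductive_reasoning"): 0.15,
        ("inductive_reasoning", "warmth"): 0.11,
        ("depression", "anxiety"): 0.10,
        ("conduct_problems", "anxiety"): 0.12,
        ("aggression", "conduct_problems"): 0.08,
        # parenting -> mental health
        ("hostility", "depression"): 0.23,
        ("hostility", "aggression"): 0.09,
        ("warmth", "depression"): -0.08,
        ("warmth", "anxiety"): -0.06,
        ("monitoring", "conduct_problems"): -0.12,
        ("harshness", "conduct_problems"): 0.15,
        ("inductive_reasoning", "anxiety"): -0.04,
        # mental health -> parenting
        ("conduct_problems", "monitoring"): -0.10,
        ("depression", "warmth"): -0.07,
        ("aggression", "inductive_reasoning"): -0.03,
        ("anxiety", "warmth"): -0.02,
    }
    for (a, b), w in edges.items():
        B[idx[a], idx[b]] = w
    return B


# Reliability targets per wave (T1, T2) in the instruments' published range;
# note harshness clears the 0.60 bar only at the second wave, so the
# both-waves exclusion rule is exercised realistically, and reliabilities
# generally improve from T1 to T2
_DEFAULT_ALPHA = {
    "warmth": (0.87, 0.87), "monitoring": (0.87, 0.88),
    "inductive_reasoning": (0.82, 0.85),
    "hostility": (0.83, 0.84), "harshness": (0.59, 0.67),
    "anxiety": (0.86, 0.87), "depression": (0.77, 0.85),
    "aggression": (0.82, 0.84), "conduct_problems": (0.65, 0.74),
}
_DEFAULT_ITEMS = {
    "warmth": 8, "monitoring": 6, "inductive_reasoning": 5,
    "hostility": 6, "harshness": 3,
    "anxiety": 20, "depression": 27, "aggression": 17, "conduct_problems": 11,
}
_DEFAULT_COV_EFFECTS = {
    ("age", "depression"): 0.04,
    ("age", "aggression"): 0.03,
    ("gender", "aggression"): 0.30,
    ("gender", "anxiety"): -0.20,
    ("maternal_education", "warmth"): 0.10,
    ("maternal_education", "harshness"): -0.08,
    ("income_band", "monitoring"): 0.08,
}


def default_spec(n: int = 591, likert_levels: int | str = 5, seed: int = 0) -> SimulationSpec:
    """The canonical 9-node two-wave spec used throughout testing.

    Deterministic: calling it twice yields identical specs.
    """
    B = _default_transition()
    tp = _default_partial()
    spec = SimulationSpec(
        true_partial=tp, B=B,
        covariate_effects=dict(_DEFAULT_COV_EFFECTS),
        items_per_scale=dict(_DEFAULT_ITEMS),
        target_alpha=dict(_DEFAULT_ALPHA),
        likert_levels=likert_levels,
        n=n, seed=seed,
    )
    sigma = spec.sigma()
    lag_var = np.diag(B.T @ sigma @ B)
    spec.innovation_sd = np.sqrt(np.maximum(1.0 - lag_var, 0.25))
    return spec.validate()


def default_scale_definitions(spec: SimulationSpec | None = None) -> list[ScaleDefinition]:
    """Item-level scale definitions matching the default spec's item counts.

    One reverse-keyed item per multi-item parenting scale keeps the
    reverse-keying path exercised end to end.
    """
    spec = spec or default_spec()
    levels = 5 if spec.likert_levels == "continuous" else int(spec.likert_levels)
    defs = []
    for node in spec.nodes:
        k = spec.items_per_scale[node]
        items = tuple(f"{node}_i{j + 1}" for j in range(k))
        reverse = (items[-1],) if (CONSTRUCTS[node] == "parenting" and k >= 4) else ()
        defs.append(ScaleDefinition(
            name=node, construct=CONSTRUCTS[node], item_ids=items,
            reverse_keyed=reverse, response_range=(1, levels),
        ))
    return defs


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "gender": rng.integers(0, 2, size=n),
        "age": rng.uniform(8.0, 17.0, size=n),
        "maternal_education": rng.choice(len(_EDU_PROBS), size=n, p=_EDU_PROBS),
        "income_band": rng.choice(len(_INCOME_PROBS), size=n, p=_INCOME_PROBS),
    })


def _covariate_shift(spec: SimulationSpec, covariates: pd.DataFrame) -> np.ndarray:
    shift = np.zeros((len(covariates), spec.p))
    idx = {nd: i for i, nd in enumerate(spec.nodes)}
    for (cov, node), slope in spec.covariate_effects.items():
        shift[:, idx[node]] += slope * covariates[cov].to_numpy(float)
    return shift


def _covariate_variance(spec: SimulationSpec) -> np.ndarray:
    """Model-implied variance contributed by the (independent) covariates."""
    cov_var = {
        "gender": 0.25,
        "age": (17.0 - 8.0) ** 2 / 12.0,
        "maternal_education": _ordinal_var(_EDU_PROBS),
        "income_band": _ordinal_var(_INCOME_PROBS),
    }
    out = np.zeros(spec.p)
    idx = {nd: i for i, nd in enumerate(spec.nodes)}
    for (cov, node), slope in spec.covariate_effects.items():
        out[idx[node]] += slope**2 * cov_var[cov]
    return out


def _ordinal_var(probs) -> float:
    levels = np.arange(len(probs))
    probs = np.asarray(probs, float)
    mu = float(levels @ probs)
    return float((levels - mu) ** 2 @ probs)


def simulate_scores(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Latent scale-level simulation: ``(scores_t1, scores_t2, covariates)``.

    Scores include the additive covariate effects; the VAR(1) dynamics act on
    the covariate-free component.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n
    sigma = spec.sigma()
    chol = np.linalg.cholesky(sigma)
    t1_latent = rng.standard_normal((n, spec.p)) @ chol.T
    innov = rng.standard_normal((n, spec.p)) * np.asarray(spec.innovation_sd, float)
    t2_latent = t1_latent @ np.asarray(spec.B, float) + innov
    covariates = _draw_covariates(n, rng)
    shift = _covariate_shift(spec, covariates)
    cols = list(spec.nodes)
    scores_t1 = pd.DataFrame(t1_latent + shift, columns=cols)
    scores_t2 = pd.DataFrame(t2_latent + shift, columns=cols)
    return scores_t1, scores_t2, covariates


def _equiprobable_cuts(levels: int) -> np.ndarray:
    from scipy.stats import norm
    return norm.ppf(np.arange(1, levels) / levels)


def _skewed_cuts(levels: int) -> np.ndarray:
    # mass concentrated in the lowest categories -> right-skewed responses
    from scipy.stats import norm
    probs = np.array([0.5**k for k in range(levels)], float)
    probs = probs / probs.sum()
    return norm.ppf(np.cumsum(probs)[:-1])


def _categorization_attenuation(cuts: np.ndarray) -> float:
    """Linear attenuation factor of a correlation under normal categorization.

    For items scored 1..L by thresholding a standard normal at ``cuts``, the
    observed Pearson correlation is approximately ``c`` times the latent one,
    with ``c = (sum phi(cuts))^2 / Var(category score)`` (the classical
    coarse-categorization result).
    """
    from scipy.stats import norm
    probs = np.diff(np.concatenate([[0.0], norm.cdf(cuts), [1.0]]))
    values = np.arange(1, len(probs) + 1)
    mu = values @ probs
    var_d = (values - mu) ** 2 @ probs
    return float(norm.pdf(cuts).sum() ** 2 / var_d)


def _generate_items(spec: SimulationSpec, scores: pd.DataFrame, total_sd: np.ndarray,
                    scale_defs: list[ScaleDefinition], wave_index: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """One-factor items per scale, Spearman-Brown-calibrated to target alpha.

    In Likert mode the latent inter-item correlation is inflated by the
    categorization attenuation factor so the *observed* item responses hit
    the target reliability — published alphas describe observed Likert items,
    not their latent continua.
    """
    n = len(scores)
    out = {}
    for si, sd_def in enumerate(scale_defs):
        node = sd_def.name
        k = len(sd_def.item_ids)
        alpha = spec.alphas_for(node)[wave_index]
        rbar = alpha / (k - alpha * (k - 1))
        if spec.likert_levels == "continuous":
            cuts = None
        else:
            levels = int(spec.likert_levels)
            cuts = (_skewed_cuts(levels) if node in spec.skewed_thresholds
                    else _equiprobable_cuts(levels))
            rbar = min(rbar / _categorization_attenuation(cuts), 0.98)
        z = scores[node].to_numpy(float) / total_sd[si]
        loading, unique = np.sqrt(rbar), np.sqrt(1.0 - rbar)
        raw = loading * z[:, None] + unique * rng.standard_normal((n, k))
        vals = raw if cuts is None else 1 + np.searchsorted(cuts, raw).astype(float)
        frame = pd.DataFrame(vals, columns=list(sd_def.item_ids))
        # store reverse-keyed items in reversed direction so scoring undoes it
        out[node] = reverse_key(frame, sd_def) if sd_def.reverse_keyed else frame
    return pd.concat(out.values(), axis=1)


def simulate_panel(spec: SimulationSpec,
                   scale_defs: list[ScaleDefinition] | None = None) -> PanelDataset:
    """Full item-level two-wave panel from a spec; deterministic given its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scores_t1, scores_t2, covariates = simulate_scores(spec, rng)
    scale_defs = scale_defs or default_scale_definitions(spec)
    cov_var = _covariate_variance(spec)
    sd_t1 = np.sqrt(1.0 + cov_var)
    sigma = spec.sigma()
    B = np.asarray(spec.B, float)
    lag_var = np.diag(B.T @ sigma @ B) + np.asarray(spec.innovation_sd, float) ** 2
    sd_t2 = np.sqrt(lag_var + cov_var)
    items = {
        "T1": _generate_items(spec, scores_t1, sd_t1, scale_defs, 0, rng),
        "T2": _generate_items(spec, scores_t2, sd_t2, scale_defs, 1, rng),
    }
    return PanelDataset(items=items, covariates=covariates,
                        scale_defs=scale_defs)


def write_panel_csv(dataset: PanelDataset, path,
                    wave_suffixes: dict[str, str] | None = None,
                    id_start: int = 1) -> None:
    """Write the wide CSV dialect that :func:`panelnet.panel_io.read_panel` ingests."""
    wave_suffixes = wave_suffixes or {"T1": "_t1", "T2": "_t2"}
    parts = {"participant_id": np.arange(id_start, id_start + dataset.n)}
    for wave, frame in dataset.items.items():
        suf = wave_suffixes[wave]
        for col in frame.columns:
            parts[f"{col}{suf}"] = frame[col].to_numpy()
    for col in dataset.covariates.columns:
        parts[col] = dataset.covariates[col].to_numpy()
    pd.DataFrame(parts).to_csv(path, index=False)


def true_networks(spec: SimulationSpec):
    """The spec's ground truth as network objects (for oracle comparisons)."""
    constructs = dict(spec.construct_partition)
    contemporaneous = ContemporaneousNetwork(
        node_labels=list(spec.nodes),
        weights=precision_to_partial(spec.precision()),
        constructs=constructs, lambda_selected=0.0, n_used=0,
        metadata={"source": "simulation ground truth"},
    )
    temporal = TemporalNetwork(
        node_labels=list(spec.nodes), d=np.asarray(spec.B, float).copy(),
        constructs=constructs, metadata={"source": "simulation ground truth"},
    )
    return contemporaneous, temporal


def true_centralities(spec: SimulationSpec) -> pd.DataFrame:
    """Ground-truth EI and in/out-prediction tables implied by the spec."""
    from .centrality import expected_influence, temporal_centrality_table

    contemporaneous, temporal = true_networks(spec)
    ei = expected_influence(contemporaneous)
    temporal_tab = temporal_centrality_table(temporal)
    return pd.concat([ei, temporal_tab], ignore_index=True)


def spec_to_yaml(spec: SimulationSpec, path=None) -> str:
    """Serialize a spec to YAML (matrices as nested lists)."""
    d = asdict(spec)
    for key in ("true_partial", "B", "innovation_sd"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["nodes"] = list(d["nodes"])
    d["skewed_thresholds"] = list(d["skewed_thresholds"])
    d["covariate_effects"] = {f"{c}::{nd}": float(v)
                              for (c, nd), v in spec.covariate_effects.items()}
    d["target_alpha"] = {k: list(spec.alphas_for(k)) for k in d["target_alpha"]}
    text = yaml.safe_dump(d, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> SimulationSpec:
    """Load a spec from a YAML string or file path."""
    if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
        with open(source) as fh:
            d = yaml.safe_load(fh)
    else:
        d = yaml.safe_load(source)
    d["nodes"] = tuple(d["nodes"])
    d["skewed_thresholds"] = tuple(d.get("skewed_thresholds") or ())
    for key in ("true_partial", "B", "innovation_sd"):
        if d.get(key) is not None:
            d[key] = np.asarray(d[key], float)
    d["covariate_effects"] = {tuple(k.split("::")): float(v)
                              for k, v in (d.get("covariate_effects") or {}).items()}
    d["target_alpha"] = {k: (tuple(v) if isinstance(v, (list, tuple)) else float(v))
                         for k, v in (d.get("target_alpha") or {}).items()}
    return SimulationSpec(**d).validate()
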