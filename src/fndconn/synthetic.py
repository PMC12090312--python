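"""Synthetic FND/HC cohort generator with planted, recoverable effects.

The generator emulates, at the connectome level, the statistical structure
the analysis assumes:

* two groups (default 85 patients / 75 controls) with demographics and
  mood/clinical score marginals matched to the study cohort's reported
  group means and SDs (moments are matched *after* truncation to each
  instrument's range, by numerically solving for the pre-truncation normal
  parameters);
* a shared link-sparsity mask; per present link, FA is a baseline
  truncated-normal plus linear age, sex and mood (BDI, STAI-T) effects —
  mood acts as a true mediator (group -> mood -> FA), so adjusting for mood
  attenuates the marginal group difference;
* a planted nodal deficit: FA on links incident to a designated region set
  is reduced by a constant delta for patients, with delta calibrated in
  closed form so the *direct* (mood-adjusted) standardized WD reduction at
  the planted nodes equals ``node_effect_d``;
* clinician-rated severity (S-FMDRS, CGI) and patient-reported physical
  functioning (SF-36) driven by one latent coupled negatively to the
  noise component of WD at two designated regions, calibrated through the
  exact monotone-transform attenuation so the correlation between severity
  and covariate-adjusted WD at those regions hits ``clinical_coupling_r``;
  S-FMDRS zeros (symptom-free patients) arise by censoring the latent's
  low-severity tail;
* streamline-count (overdispersed, proportional to FA) and mean-fiber-length
  connectomes on the same mask.

Everything is reproducible: one ``numpy`` Generator seeded from the call
drives every draw, and identical (config, seed) yield bit-identical output.
The emitted GroundTruth records the planted node set, the per-link FA
deficit, and the coupling coefficients, for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import least_squares

from .connectome_io import (
    N_REGIONS,
    SubjectConnectome,
    ValidationError,
    region_names,
    validate_cohort,
)
from .graph_metrics import link_index_pairs

#: the 19 regions with reduced WD in the age/sex-adjusted comparison,
#: used as the default planted node set
PLANTED_19 = (
    "ctx-rh-lateralorbitofrontal",
    "ctx-lh-insula",
    "ctx-rh-insula",
    "ctx-rh-middletemporal",
    "ctx-rh-transversetemporal",
    "ctx-lh-inferiortemporal",
    "ctx-lh-superiortemporal",
    "ctx-rh-superiortemporal",
    "ctx-lh-parahippocampal",
    "ctx-rh-postcentral",
    "ctx-lh-inferiorparietal",
    "ctx-rh-inferiorparietal",
    "ctx-lh-lateraloccipital",
    "Left-Putamen",
    "Right-Putamen",
    "Right-Caudate",
    "ctx-lh-superiorparietal",
    "ctx-lh-precuneus",
    "Right-Cerebellum-Cortex",
)

#: regions whose WD drives clinical severity
COUPLED_DEFAULT = ("ctx-lh-precuneus", "ctx-lh-superiorparietal")

#: reported cohort score moments: ((FND mean, sd), (HC mean, sd)), instrument range
GROUP_SCORE_MOMENTS = {
    "age": ((37.55, 14.26), (33.13, 10.97), (18.0, 80.0)),
    "bdi": ((14.33, 9.96), (4.41, 6.13), (0.0, 63.0)),
    "stai_state": ((37.04, 10.91), (31.76, 7.15), (20.0, 80.0)),
    "stai_trait": ((45.22, 12.92), (33.93, 7.13), (20.0, 80.0)),
    "sf36_physical_health": ((30.59, 35.64), (93.0, 23.09), (0.0, 100.0)),
    "sf36_mental_health": ((58.92, 23.17), (76.53, 13.69), (0.0, 100.0)),
    "sf36_general_health": ((47.59, 20.90), (79.33, 14.67), (0.0, 100.0)),
    "sf36_physical_functioning": ((64.24, 25.12), (97.33, 6.06), (0.0, 100.0)),
}
FEMALE_FRAC = {"FND": 63 / 85, "HC": 55 / 75}
SFMDRS_MOMENTS = (8.54, 9.65)      # marginal incl. zeros
SFMDRS_RANGE = (0.5, 54.0)         # positive part
CGI_MOMENTS = (2.69, 1.59)
ILLNESS_YEARS_MOMENTS = (4.89, 6.08)
MEDICATION_RATE_FND = 0.45         # any psychotropic; probability rises with BDI


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the generative model; the defaults are the study conditions."""

    n_fnd: int = 85
    n_hc: int = 75
    baseline_fa_mean: float = 0.40
    baseline_fa_sd: float = 0.08
    link_density: float = 0.6
    planted_nodes: tuple[str, ...] = PLANTED_19
    node_effect_d: float = 1.0
    age_slope_per_year: float = -0.001
    sex_offset: float = 0.005
    mediator_coupling_bdi: float = -0.002
    mediator_coupling_stait: float = -0.001
    clinical_coupling_r: float = -0.5
    coupled_nodes: tuple[str, ...] = COUPLED_DEFAULT
    sfmdrs_zero_prob: float = 21 / 85
    nstream_scale: float = 2000.0
    nstream_dispersion: float = 5.0
    mean_length_mm: float = 60.0
    mean_length_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_fnd, self.n_hc) < 3:
            raise ValidationError("need at least 3 subjects per group")
        for name in ("link_density", "sfmdrs_zero_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        names = set(region_names())
        for attr in ("planted_nodes", "coupled_nodes"):
            unknown = set(getattr(self, attr)) - names
            if unknown:
                raise ValidationError(f"{attr} contains unknown region(s): {sorted(unknown)}")
        if not -1.0 <= self.clinical_coupling_r <= 1.0:
            raise ValidationError("clinical_coupling_r must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_nodes"] = list(self.planted_nodes)
        d["coupled_nodes"] = list(self.coupled_nodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("planted_nodes", "coupled_nodes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def save_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Generative parameters a recovery test needs, as emitted by the generator."""

    planted_nodes: tuple[str, ...]
    fa_deficit_delta: float
    planted_link_indices: list[int]
    node_effect_d: float
    coupled_nodes: tuple[str, ...]
    clinical_coupling_r: float
    coupling_alpha: float
    transform_attenuation: float
    mediator_paths: dict[str, float]
    present_link_indices: list[int] = field(repr=False, default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["planted_nodes"] = list(d["planted_nodes"])
        d["coupled_nodes"] = list(d["coupled_nodes"])
        path.write_text(json.dumps(d, indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# truncated-normal moment matching
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def fit_truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose [lo, hi]-truncated moments match (mean, sd).

    Solved numerically; when the target is outside what a truncated normal
    can reach (very skewed bounded scores), the fit minimizes a weighted
    moment error that prioritizes the mean.
    """
    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def resid(params):
        m, s = moments(params)
        return [10.0 * (m - mean) / max(sd, 1e-6), (s - sd) / max(sd, 1e-6)]

    sol = least_squares(resid, x0=[mean, np.log(max(sd, 1e-3))], xtol=1e-14, ftol=1e-14)
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _truncnorm_frozen(mean: float, sd: float, lo: float, hi: float):
    mu, sigma = fit_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def _sample_matched(rng: np.random.Generator, n: int, mean: float, sd: float,
                    lo: float, hi: float) -> np.ndarray:
    return _truncnorm_frozen(mean, sd, lo, hi).rvs(size=n, random_state=rng)


def _transform_attenuation(g, grid_size: int = 8192) -> float:
    """corr(g(L), L) for standard normal L and monotone g, by quantile quadrature.

    This is the exact factor by which a monotone marginal transform of a
    latent Gaussian attenuates its Pearson correlation with any jointly
    Gaussian variable.
    """
    u = (np.arange(grid_size) + 0.5) / grid_size
    L = stats.norm.ppf(u)
    G = np.asarray(g(L), dtype=float)
    Gc, Lc = G - G.mean(), L - L.mean()
    denom = np.sqrt((Gc ** 2).sum() * (Lc ** 2).sum())
    return float((Gc * Lc).sum() / denom) if denom > 0 else 0.0


def _sfmdrs_transform(zero_prob: float):
    """Monotone map latent N(0,1) -> zero-censored S-FMDRS marginal."""
    mean, sd = SFMDRS_MOMENTS
    p_pos = 1.0 - zero_prob
    if p_pos <= 0:
        return lambda latent: np.zeros_like(np.asarray(latent, dtype=float))
    mean_pos = mean / p_pos
    var_pos = (mean ** 2 + sd ** 2) / p_pos - mean_pos ** 2
    sd_pos = np.sqrt(max(var_pos, 1.0))
    dist = _truncnorm_frozen(mean_pos, sd_pos, *SFMDRS_RANGE)

    def g(latent):
        u = stats.norm.cdf(np.asarray(latent, dtype=float))
        out = np.zeros_like(u)
        pos = u > zero_prob
        out[pos] = dist.ppf((u[pos] - zero_prob) / p_pos)
        return out

    return g


# ---------------------------------------------------------------------------
# core generation
# ---------------------------------------------------------------------------

def _generate_core(config: GeneratorConfig, rng: np.random.Generator):
    """Draw cohort, link mask, FA link values, WD table and ground truth.

    Returns (cohort, fa_links (n x n_present), present (bool 3486), wd,
    ground_truth). Matrix assembly and the other weight kinds live in
    ``generate_cohort`` so large simulations can skip them.
    """
    n1, n2 = config.n_fnd, config.n_hc
    n = n1 + n2
    names = region_names()
    name_to_idx = {name: i for i, name in enumerate(names)}
    group = np.array(["FND"] * n1 + ["HC"] * n2)
    fnd = group == "FND"

    def per_group(key):
        (m1, s1), (m2, s2), (lo, hi) = GROUP_SCORE_MOMENTS[key]
        a = _sample_matched(rng, n1, m1, s1, lo, hi)
        b = _sample_matched(rng, n2, m2, s2, lo, hi)
        return np.concatenate([a, b])

    age = per_group("age")
    sex = np.where(
        np.concatenate([rng.random(n1) < FEMALE_FRAC["FND"],
                        rng.random(n2) < FEMALE_FRAC["HC"]]),
        "female", "male")
    bdi = per_group("bdi")
    stai_state = per_group("stai_state")
    stai_trait = per_group("stai_trait")

    # medication: any-psychotropic flag, more likely for more depressed patients
    z_bdi = (bdi[:n1] - bdi[:n1].mean()) / max(bdi[:n1].std(), 1e-9)
    logit = np.log(MEDICATION_RATE_FND / (1 - MEDICATION_RATE_FND)) + 0.8 * z_bdi
    medication = np.concatenate([rng.random(n1) < 1 / (1 + np.exp(-logit)),
                                 np.zeros(n2, dtype=bool)])

    # shared sparsity mask over the 3486 candidate links
    pairs = link_index_pairs()
    present = rng.random(len(pairs)) < config.link_density
    pairs_p = pairs[present]
    n_present = int(present.sum())
    # incidence of present links on nodes
    inc = np.zeros((N_REGIONS, n_present))
    cols = np.arange(n_present)
    inc[pairs_p[:, 0], cols] = 1.0
    inc[pairs_p[:, 1], cols] = 1.0
    deg = inc.sum(axis=1)

    # per-subject systematic FA shift (identical across a subject's links)
    male = (sex == "male").astype(float)
    systematic = (config.baseline_fa_mean
                  + config.age_slope_per_year * (age - age.mean())
                  + config.sex_offset * male
                  + config.mediator_coupling_bdi * (bdi - bdi.mean())
                  + config.mediator_coupling_stait * (stai_trait - stai_trait.mean()))

    # delta calibration: direct standardized WD effect at planted nodes.
    # Within-group WD variance at a node of present degree m:
    #   m * fa_sd^2  (independent link noise)  +  m^2 * var_w(systematic)
    # where var_w is the pooled within-group variance of the subject shift.
    planted_idx = np.array(sorted(name_to_idx[p] for p in config.planted_nodes), dtype=int)
    delta = 0.0
    if len(planted_idx) and config.node_effect_d != 0:
        var_sys = (np.var(systematic[fnd], ddof=1) * (n1 - 1)
                   + np.var(systematic[~fnd], ddof=1) * (n2 - 1)) / (n - 2)
        m = deg[planted_idx]
        sigma_wd = np.sqrt(m * config.baseline_fa_sd ** 2 + m ** 2 * var_sys)
        ratio = np.mean(m / sigma_wd)
        delta = config.node_effect_d / ratio
        delta_max = config.baseline_fa_mean - 0.05
        if delta > delta_max:
            raise ValidationError(
                f"node_effect_d={config.node_effect_d} needs FA deficit {delta:.3f}, beyond the "
                f"attainable maximum d={delta_max * ratio:.2f} within the FA bounds")

    planted_link = np.zeros(n_present, dtype=bool)
    if len(planted_idx):
        planted_link = np.isin(pairs_p[:, 0], planted_idx) | np.isin(pairs_p[:, 1], planted_idx)

    eps = rng.normal(0.0, config.baseline_fa_sd, size=(n, n_present))
    fa_links = eps + systematic[:, None]
    if delta:
        fa_links[np.ix_(fnd, planted_link)] -= delta
    np.clip(fa_links, 0.01, 0.95, out=fa_links)

    # clinical severity latent, coupled to the noise component of WD at the
    # coupled nodes (the component that survives covariate adjustment)
    sf36 = {key: per_group(key) for key in
            ("sf36_physical_health", "sf36_mental_health", "sf36_general_health")}
    coupled_idx = np.array([name_to_idx[c] for c in config.coupled_nodes], dtype=int)
    wd_noise_fnd = eps[fnd] @ inc[coupled_idx].T           # (n1, n_coupled)
    sds = wd_noise_fnd.std(axis=0, ddof=1)
    z0 = (wd_noise_fnd / np.where(sds > 0, sds, 1.0)).sum(axis=1)
    z = (z0 - z0.mean()) / max(z0.std(ddof=1), 1e-12)

    g_sfmdrs = _sfmdrs_transform(config.sfmdrs_zero_prob)
    kappa = _transform_attenuation(g_sfmdrs)
    target = abs(config.clinical_coupling_r)
    alpha = 0.0
    if target > 0 and len(coupled_idx):
        # population correlation between the summed-z latent and each coupled
        # node's WD noise: nodes k, l share the single link (k, l) when present,
        # so corr(v_k, v_l) = present(k,l) / sqrt(m_k m_l)
        m_c = deg[coupled_idx]
        R = np.eye(len(coupled_idx))
        for a in range(len(coupled_idx)):
            for b in range(a + 1, len(coupled_idx)):
                i, j = sorted((coupled_idx[a], coupled_idx[b]))
                shared = bool(np.any((pairs_p[:, 0] == i) & (pairs_p[:, 1] == j)))
                R[a, b] = R[b, a] = shared / np.sqrt(m_c[a] * m_c[b])
        c_k = R.sum(axis=1) / np.sqrt(R.sum())
        reachable = kappa * float(np.mean(c_k))
        alpha = target / reachable if reachable > 0 else np.inf
        if alpha > 1.0:
            raise ValidationError(
                f"clinical_coupling_r={config.clinical_coupling_r} unreachable; attainable "
                f"|r| maximum is {reachable:.3f}")
    # severity latent rises as coupled-node WD falls when the target r is negative
    sign = -1.0 if config.clinical_coupling_r < 0 else 1.0
    latent = sign * alpha * z + np.sqrt(max(1 - alpha ** 2, 0.0)) * rng.standard_normal(n1)

    sfmdrs = g_sfmdrs(latent)
    cgi = np.clip(np.rint(CGI_MOMENTS[0] + CGI_MOMENTS[1] * latent), 0, 7)
    # SF-36 physical functioning: better function <-> lower severity latent (FND);
    # independent ceiling-matched marginal for HC
    (pf1, pf2, pf_rng) = GROUP_SCORE_MOMENTS["sf36_physical_functioning"]
    pf_fnd = _truncnorm_frozen(pf1[0], pf1[1], *pf_rng).ppf(stats.norm.cdf(-latent))
    pf_hc = _sample_matched(rng, n2, pf2[0], pf2[1], *pf_rng)

    mu_y = np.log(ILLNESS_YEARS_MOMENTS[0]) - 0.5 * np.log(
        1 + (ILLNESS_YEARS_MOMENTS[1] / ILLNESS_YEARS_MOMENTS[0]) ** 2)
    sd_y = np.sqrt(np.log(1 + (ILLNESS_YEARS_MOMENTS[1] / ILLNESS_YEARS_MOMENTS[0]) ** 2))
    illness_months = 12.0 * rng.lognormal(mu_y, sd_y, size=n1)

    width = max(3, len(str(n)))
    subject_id = ([f"fnd{i + 1:0{width}d}" for i in range(n1)]
                  + [f"hc{i + 1:0{width}d}" for i in range(n2)])
    nan2 = np.full(n2, np.nan)
    cohort = pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "age": age,
        "sex": sex,
        "medication_any_psychotropic": medication,
        "bdi": bdi,
        "stai_state": stai_state,
        "stai_trait": stai_trait,
        "sf36_physical_health": sf36["sf36_physical_health"],
        "sf36_mental_health": sf36["sf36_mental_health"],
        "sf36_general_health": sf36["sf36_general_health"],
        "sf36_physical_functioning": np.concatenate([pf_fnd, pf_hc]),
        "sfmdrs": np.concatenate([sfmdrs, nan2]),
        "cgi": np.concatenate([cgi, nan2]),
        "illness_duration_months": np.concatenate([illness_months, nan2]),
    })
    cohort = validate_cohort(cohort)

    wd = pd.DataFrame(fa_links @ inc.T, columns=names,
                      index=pd.Index(subject_id, name="subject_id"))

    truth = GroundTruth(
        planted_nodes=tuple(config.planted_nodes),
        fa_deficit_delta=float(delta),
        planted_link_indices=[int(i) for i in np.flatnonzero(present)[planted_link]],
        node_effect_d=float(config.node_effect_d),
        coupled_nodes=tuple(config.coupled_nodes),
        clinical_coupling_r=float(config.clinical_coupling_r),
        coupling_alpha=float(alpha),
        transform_attenuation=float(kappa),
        mediator_paths={
            "bdi_per_link": float(config.mediator_coupling_bdi),
            "stai_trait_per_link": float(config.mediator_coupling_stait),
            "age_per_link": float(config.age_slope_per_year),
            "sex_per_link": float(config.sex_offset),
        },
        present_link_indices=[int(i) for i in np.flatnonzero(present)],
    )
    return cohort, fa_links, present, wd, truth


def generate_tables(config: GeneratorConfig, seed: int | None = None):
    """Lightweight generation: (wd table, fa link values, present mask, cohort, truth).

    ``fa link values`` is an (n_subjects, 3486) array in canonical link
    order with zeros on absent links. Used by simulations that do not need
    full 84x84 matrices.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort, fa_links, present, wd, truth = _generate_core(config, rng)
    full = np.zeros((len(cohort), present.size))
    full[:, present] = fa_links
    return wd, full, present, cohort, truth


def generate_cohort(config: GeneratorConfig, seed: int | None = None,
                    weight_kinds: tuple[str, ...] = ("fa", "nstreamlines", "mean_length_mm")):
    """Generate a full synthetic cohort.

    Returns ``(connectomes, cohort, truth)`` where ``connectomes`` maps each
    requested weight kind to a list of SubjectConnectome. FA is always drawn
    first, so the FA data for a given (config, seed) is identical whichever
    other kinds are requested.
    """
    unknown = [k for k in weight_kinds if k not in ("fa", "nstreamlines", "mean_length_mm")]
    if unknown:
        raise ValidationError(f"unknown weight kind(s) {unknown}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort, fa_links, present, _, truth = _generate_core(config, rng)
    n = len(cohort)
    iu = np.triu_indices(N_REGIONS, k=1)
    iu_p = (iu[0][present], iu[1][present])
    ids = list(cohort["subject_id"])

    def to_matrices(link_vals: np.ndarray, kind: str) -> list[SubjectConnectome]:
        out = []
        for s in range(n):
            mat = np.zeros((N_REGIONS, N_REGIONS))
            mat[iu_p] = link_vals[s]
            mat = mat + mat.T
            out.append(SubjectConnectome(subject_id=ids[s], weight_kind=kind, matrix=mat))
        return out

    connectomes: dict[str, list[SubjectConnectome]] = {}
    if "fa" in weight_kinds:
        connectomes["fa"] = to_matrices(fa_links, "fa")
    if "nstreamlines" in weight_kinds:
        mu = np.maximum(config.nstream_scale * fa_links, 1.0)
        k = config.nstream_dispersion
        counts = rng.negative_binomial(k, k / (k + mu)).astype(float)
        counts = np.maximum(counts, 1.0)  # present links carry at least one streamline
        connectomes["nstreamlines"] = to_matrices(counts, "nstreamlines")
    if "mean_length_mm" in weight_kinds:
        lengths = rng.normal(config.mean_length_mm, config.mean_length_sd,
                             size=fa_links.shape)
        np.clip(lengths, 5.0, 250.0, out=lengths)
        connectomes["mean_length_mm"] = to_matrices(lengths, "mean_length_mm")
    return connectomes, cohort, truth


def default_scenarios() -> dict[str, GeneratorConfig]:
    """Named presets for the standard study conditions.

    * ``null`` — no planted effects of any kind (type-I-error calibration).
    * ``paper_like`` — the default study conditions: 19 planted regions,
      mood mediation on, severity coupled to two parietal regions.
    * ``strong_effect`` — the same structure with a larger direct deficit.
    * ``mediation_off`` — planted deficit without the mood-mediated path.
    """
    base = GeneratorConfig()
    return {
        "null": replace(base, planted_nodes=(), node_effect_d=0.0,
                        mediator_coupling_bdi=0.0, mediator_coupling_stait=0.0,
                        clinical_coupling_r=0.0),
        "paper_like": base,
        "strong_effect": replace(base, node_effect_d=1.5),
        "mediation_off": replace(base, mediator_coupling_bdi=0.0,
                                 mediator_coupling_stait=0.0),
    }
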