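"""Synthetic twin-cohort generation.

Generates cohorts with exactly the covariance structure the biometrical
twin models assume: per-pair latent A/D (or C)/E components drawn jointly
from the implied multivariate normal, with cross-twin correlations of 1
(MZ) or 1/2 and 1/4 (DZ) for additive and dominance factors, C shared
fully, E uncorrelated, an opposite-sex genetic correlation r_fm,
sex-specific paths and total variances, and age effects on means.  Layered
on top: cross-trait component correlations (bivariate cohorts), path
moderation by a twin's own moderator value (G×E cohorts), binary deficit
items generating a right-skewed frailty index, and singleton/missingness
injection.

Default parameter values emulate the study conditions the models target: a
frailty index (FI) with median ≈ 0.11, higher heritability and total
variance in women than men, an approximately normal BMI-like and
education-years-like trait, and ages uniform on 41–99 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Cohort, GROUP_SEXES, SAME_SEX_GROUPS, ZYGOSITY_GROUPS

_AGE_CENTER = 70.0  # midpoint of the default 41–99 age range


@dataclass
class TraitTruth:
    """Generating truth for one phenotype.

    ``shares`` are standardized (a², d²-or-c², e²) per sex and must sum
    to 1; ``total_var`` is in squared phenotype units.  The mean model is
    ``mean + age_slope·(age−70) + age_quad·(age−70)²`` per sex.
    """

    name: str
    family: str = "ADE"                       # ADE or ACE
    shares: dict = field(default_factory=lambda: {
        "M": (0.30, 0.15, 0.55), "F": (0.35, 0.15, 0.50)})
    total_var: dict = field(default_factory=lambda: {"M": 1.0, "F": 1.0})
    mean: dict = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    age_slope: float = 0.0
    age_quad: float = 0.0

    def __post_init__(self):
        if self.family not in ("ADE", "ACE", "AE"):
            raise ValueError("trait family must be ADE, ACE or AE")
        for s, sh in self.shares.items():
            if any(v < 0 for v in sh) or abs(sum(sh) - 1.0) > 1e-8:
                raise ValueError(f"shares for sex {s} must be non-negative and sum to 1")
            if self.family == "AE" and sh[1] != 0:
                raise ValueError("AE traits must have a zero second share")

    def paths(self, sex: str) -> tuple[float, float, float]:
        a2, dc2, e2 = self.shares[sex]
        V = self.total_var[sex]
        return (np.sqrt(a2 * V), np.sqrt(dc2 * V), np.sqrt(e2 * V))


@dataclass
class CrossTraitTruth:
    """Component correlations between two traits (correlated-factor truth)."""

    r_A: float = 0.0
    r_DC: float = 0.0
    r_E: float = 0.0

    def __post_init__(self):
        for r in (self.r_A, self.r_DC, self.r_E):
            if abs(r) > 1:
                raise ValueError("cross-trait component correlations must lie in [-1, 1]")


@dataclass
class ModerationTruth:
    """Generating truth for a G×E (path-moderation) cohort.

    The moderated trait is built from the moderator's latent components
    (common paths) plus its own latents (unique paths); every path is a
    linear function ``path0 + beta·m`` of the twin's own centered moderator
    value (``|m|`` instead when ``abs_moderator`` is set, producing
    U-shaped variance over the moderator).
    """

    common0: tuple = (0.3, 0.0, 0.1)     # (aC, dC/cC, eC) intercepts
    unique0: tuple = (0.5, 0.0, 0.6)     # (aU, dU/cU, eU) intercepts
    beta_common: tuple = (0.0, 0.0, 0.0)
    beta_unique: tuple = (0.0, 0.0, 0.0)
    abs_moderator: bool = False


@dataclass
class DeficitConfig:
    """Binary deficit-item generator for the frailty index.

    Items are endorsed when ``loading·liability + noise`` exceeds a
    per-item threshold.  Thresholds are expressed through per-item
    endorsement probabilities at median liability; their mean sets the
    cohort's median FI (default grid averages 0.11).
    """

    n_items: int = 44
    loading: float = 0.8
    endorse_probs: np.ndarray | None = None   # default linspace(0.01, 0.21)
    item_missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if not 0 <= self.item_missing_rate < 1:
            raise ValueError("item_missing_rate must be in [0, 1)")
        if self.endorse_probs is None:
            self.endorse_probs = np.linspace(0.01, 0.21, self.n_items)
        self.endorse_probs = np.asarray(self.endorse_probs, dtype=float)
        if self.endorse_probs.shape != (self.n_items,):
            raise ValueError("endorse_probs must have length n_items")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic twin cohort."""

    n_pairs: dict | int = 1000               # per zygosity group
    traits: list = field(default_factory=list)
    r_fm: float = 1.0
    r_fm_scope: str = "joint"                 # scale A and D OS terms jointly, or A only
    cross: CrossTraitTruth | None = None
    moderation: ModerationTruth | None = None
    age_range: tuple = (41.0, 99.0)
    singleton_fraction: float = 0.0
    seed: int = 0

    def group_sizes(self, groups=ZYGOSITY_GROUPS) -> dict:
        if isinstance(self.n_pairs, int):
            return {g: self.n_pairs for g in groups}
        return {g: n for g, n in self.n_pairs.items() if n > 0}

    def __post_init__(self):
        if abs(self.r_fm) > 1:
            raise ValueError("r_fm must lie in [-1, 1]")
        if not 0 <= self.singleton_fraction < 1:
            raise ValueError("singleton_fraction must be in [0, 1)")


def default_study_config(n_pairs=2000, seed: int = 0) -> GeneratorConfig:
    """Generator defaults emulating the target study conditions.

    FI: ADE with female shares 0.41/0.11/0.48 (H=52%) and male
    0.00/0.45/0.55 (H=45%), female total variance above male, right-skew
    delegated to the deficit layer.  BMI-like: ADE, H 69% (F) / 66% (M),
    means 24.5/25.5 kg/m², quadratic age trend.  Education-like: ACE with
    common-environment shares 29% (F) / 25% (M), mean 10.5 years.
    """
    fi = TraitTruth(
        name="FI", family="ADE",
        shares={"M": (0.00, 0.45, 0.55), "F": (0.41, 0.11, 0.48)},
        total_var={"M": 0.0056, "F": 0.0090},
        mean={"M": 0.105, "F": 0.125},
        age_slope=0.0022, age_quad=0.0)
    bmi = TraitTruth(
        name="BMI", family="ADE",
        shares={"M": (0.40, 0.26, 0.34), "F": (0.45, 0.24, 0.31)},
        total_var={"M": 3.1 ** 2, "F": 3.8 ** 2},
        mean={"M": 25.5, "F": 24.5},
        age_slope=0.04, age_quad=-0.004)
    edu = TraitTruth(
        name="EDU", family="ACE",
        shares={"M": (0.42, 0.25, 0.33), "F": (0.40, 0.29, 0.31)},
        total_var={"M": 3.2 ** 2, "F": 3.3 ** 2},
        mean={"M": 10.5, "F": 10.4},
        age_slope=-0.08, age_quad=-0.002)
    return GeneratorConfig(n_pairs=n_pairs, traits=[fi, bmi, edu], r_fm=1.0,
                           seed=seed)


# ---------------------------------------------------------------------------
# latent sampling


def _component_kappa(group: str, comp: str, family: str, r_fm: float,
                     scope: str) -> float:
    """Cross-twin correlation of one latent component in one group."""
    mz = group in ("MZM", "MZF")
    if comp == "A":
        k = 1.0 if mz else 0.5
        if group == "DZOS":
            k *= r_fm
        return k
    if comp == "DC":
        if family == "ACE":
            return 1.0
        k = 1.0 if mz else 0.25
        if group == "DZOS" and scope == "joint":
            k *= r_fm
        return k
    return 0.0  # E


def _draw_pair_component(rng, n, kappa):
    """(n, 2) standard-normal latent pairs with cross-twin correlation kappa."""
    if abs(kappa) > 1 + 1e-12:
        raise ValueError("implied cross-twin correlation outside [-1, 1]")
    z1 = rng.standard_normal(n)
    z2 = kappa * z1 + np.sqrt(max(0.0, 1 - kappa ** 2)) * rng.standard_normal(n)
    return np.column_stack([z1, z2])


def _draw_bivariate_component(rng, n, kappa, r):
    """(n, 4) latents (X1, Y1, X2, Y2): cross-trait corr r, cross-twin kappa.

    The 4×4 correlation is the Kronecker product of the twin block
    [[1, κ], [κ, 1]] and the trait block [[1, r], [r, 1]]; positive
    semidefinite whenever |κ| ≤ 1 and |r| ≤ 1, enforced before sampling.
    """
    if abs(r) > 1 or abs(kappa) > 1:
        raise ValueError("implied 4x4 latent covariance not positive semidefinite")
    twin = np.array([[1.0, kappa], [kappa, 1.0]])
    trait = np.array([[1.0, r], [r, 1.0]])
    cov = np.kron(twin, trait)  # order (t1X, t1Y, t2X, t2Y)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    z = rng.standard_normal((n, 4)) @ root.T
    return z[:, [0, 1, 2, 3]]


def _base_frame(rng, group, n, age_range, id_prefix):
    lo, hi = age_range
    ages = rng.uniform(lo, hi, size=n)
    s1, s2 = GROUP_SEXES[group]
    return pd.DataFrame({
        "pair_id": [f"{id_prefix}{group}-{i:06d}" for i in range(n)],
        "zygosity_group": group, "sex1": s1, "sex2": s2,
        "age": ages, "present1": True, "present2": True,
    })


def _mean_vec(trait: TraitTruth, sex: str, ages: np.ndarray) -> np.ndarray:
    ac = ages - _AGE_CENTER
    return trait.mean[sex] + trait.age_slope * ac + trait.age_quad * ac ** 2


# ---------------------------------------------------------------------------
# public generators


def simulate_univariate(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Single-trait (or independent multi-trait) cohort with the specified
    A/D-or-C/E structure per zygosity group.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if not config.traits:
        raise ValueError("config.traits is empty")
    frames = []
    for group, n in config.group_sizes().items():
        df = _base_frame(rng, group, n, config.age_range, "u")
        ages = df["age"].to_numpy()
        for trait in config.traits:
            vals = np.zeros((n, 2))
            for ci, comp in enumerate(("A", "DC", "E")):
                kappa = _component_kappa(group, comp, trait.family,
                                         config.r_fm, config.r_fm_scope)
                z = _draw_pair_component(rng, n, kappa)
                for col, sex in enumerate(GROUP_SEXES[group]):
                    vals[:, col] += trait.paths(sex)[ci] * z[:, col]
            for col, sex in enumerate(GROUP_SEXES[group]):
                vals[:, col] += _mean_vec(trait, sex, ages)
            df[trait.name + "_1"], df[trait.name + "_2"] = vals[:, 0], vals[:, 1]
        frames.append(df)
    cohort = Cohort(pd.concat(frames, ignore_index=True),
                    [t.name for t in config.traits])
    if config.singleton_fraction > 0:
        cohort = inject_missing(cohort, config.singleton_fraction, 0.0,
                                seed=rng.integers(2 ** 31))
    return cohort


def simulate_bivariate(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Two-trait cohort whose like components correlate r_A / r_D-or-C / r_E
    across traits, with the usual zygosity rules across twins.

    Defaults to same-sex groups only (the setting in which bivariate
    sex-limitation models are fitted); pass explicit ``n_pairs`` per group
    to include opposite-sex pairs.
    """
    if config.cross is None or len(config.traits) != 2:
        raise ValueError("bivariate simulation needs two traits and a cross block")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tX, tY = config.traits
    if tX.family != tY.family:
        raise ValueError("both traits must share a family (ADE or ACE)")
    rs = {"A": config.cross.r_A, "DC": config.cross.r_DC, "E": config.cross.r_E}
    sizes = (config.group_sizes(SAME_SEX_GROUPS)
             if isinstance(config.n_pairs, int) else config.group_sizes())
    frames = []
    for group, n in sizes.items():
        df = _base_frame(rng, group, n, config.age_range, "b")
        ages = df["age"].to_numpy()
        valsX, valsY = np.zeros((n, 2)), np.zeros((n, 2))
        for ci, comp in enumerate(("A", "DC", "E")):
            kappa = _component_kappa(group, comp, tX.family, config.r_fm,
                                     config.r_fm_scope)
            z = _draw_bivariate_component(rng, n, kappa, rs[comp])
            for col, sex in enumerate(GROUP_SEXES[group]):
                valsX[:, col] += tX.paths(sex)[ci] * z[:, 2 * col]
                valsY[:, col] += tY.paths(sex)[ci] * z[:, 2 * col + 1]
        for col, sex in enumerate(GROUP_SEXES[group]):
            valsX[:, col] += _mean_vec(tX, sex, ages)
            valsY[:, col] += _mean_vec(tY, sex, ages)
        df[tX.name + "_1"], df[tX.name + "_2"] = valsX[:, 0], valsX[:, 1]
        df[tY.name + "_1"], df[tY.name + "_2"] = valsY[:, 0], valsY[:, 1]
        frames.append(df)
    cohort = Cohort(pd.concat(frames, ignore_index=True), [tX.name, tY.name])
    if config.singleton_fraction > 0:
        cohort = inject_missing(cohort, config.singleton_fraction, 0.0,
                                seed=rng.integers(2 ** 31))
    return cohort


def simulate_multitrait(config: GeneratorConfig, cross: dict | None = None,
                        seed: int | None = None) -> Cohort:
    """Joint cohort of several traits with cross-trait component correlations.

    ``cross`` maps component class ("A", "DC", "E") to a T×T correlation
    matrix among trait loadings on that class.  The second component class
    is D for ADE traits and C for ACE traits; cross-trait "DC" entries are
    only allowed between traits of the same family (the latent classes
    differ otherwise) and must be zero across families.  Cross-twin,
    cross-trait latent covariance is the kinship weight times the trait
    correlation.  Generates all groups in ``config.n_pairs``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits = config.traits
    T = len(traits)
    R = {comp: np.eye(T) for comp in ("A", "DC", "E")}
    if cross:
        for comp, mat in cross.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (T, T) or not np.allclose(mat, mat.T):
                raise ValueError(f"cross[{comp!r}] must be a symmetric {T}x{T} matrix")
            R[comp] = mat
    for j in range(T):
        for k in range(j + 1, T):
            if traits[j].family != traits[k].family and abs(R["DC"][j, k]) > 0:
                raise ValueError("cross-family D/C correlations are not defined; "
                                 "set them to zero")
    frames = []
    for group, n in config.group_sizes().items():
        df = _base_frame(rng, group, n, config.age_range, "s")
        ages = df["age"].to_numpy()
        vals = np.zeros((n, 2, T))
        for ci, comp in enumerate(("A", "DC", "E")):
            kap = np.array([
                _component_kappa(group, comp, t.family, config.r_fm,
                                 config.r_fm_scope) for t in traits])
            within = R[comp]
            # same-family traits share the kinship weight exactly; cross-family
            # R entries are zero, so a simple equal-kappa mask suffices
            eq = np.abs(kap[:, None] - kap[None, :]) < 1e-12
            cross_tw = np.where(eq, kap[:, None], 0.0) * within
            cov = np.block([[within, cross_tw], [cross_tw.T, within]])
            w, v = np.linalg.eigh(cov)
            if w.min() < -1e-8:
                raise ValueError(f"implied latent covariance for {comp} not PSD")
            root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
            z = rng.standard_normal((n, 2 * T)) @ root.T
            for col, sex in enumerate(GROUP_SEXES[group]):
                for j, t in enumerate(traits):
                    vals[:, col, j] += t.paths(sex)[ci] * z[:, col * T + j]
        for col, sex in enumerate(GROUP_SEXES[group]):
            for j, t in enumerate(traits):
                vals[:, col, j] += _mean_vec(t, sex, ages)
        for j, t in enumerate(traits):
            df[t.name + "_1"] = vals[:, 0, j]
            df[t.name + "_2"] = vals[:, 1, j]
        frames.append(df)
    cohort = Cohort(pd.concat(frames, ignore_index=True), [t.name for t in traits])
    if config.singleton_fraction > 0:
        cohort = inject_missing(cohort, config.singleton_fraction, 0.0,
                                seed=int(rng.integers(2 ** 31)))
    return cohort


def simulate_moderated(config: GeneratorConfig, moderator_name: str | None = None,
                       seed: int | None = None) -> Cohort:
    """G×E cohort: moderator generated as a heritable trait, moderated trait
    built from moderator-shared (common) and trait-specific (unique) latent
    components whose path coefficients vary with the twin's own moderator.

    With all moderation betas zero this reduces to an unmoderated bivariate
    structure.  ``config.traits`` must be [moderated trait, moderator]; the
    moderated trait's variance structure comes from ``config.moderation``.
    """
    if config.moderation is None or len(config.traits) != 2:
        raise ValueError("moderated simulation needs two traits and a moderation block")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trait, mod = config.traits
    if moderator_name is not None and mod.name != moderator_name:
        raise ValueError(f"moderator trait {moderator_name!r} not second in traits")
    mt = config.moderation
    sizes = (config.group_sizes(SAME_SEX_GROUPS)
             if isinstance(config.n_pairs, int) else config.group_sizes())
    frames = []
    for group, n in sizes.items():
        df = _base_frame(rng, group, n, config.age_range, "m")
        ages = df["age"].to_numpy()
        modvals = np.zeros((n, 2))
        zM = {}
        for ci, comp in enumerate(("A", "DC", "E")):
            kappa = _component_kappa(group, comp, mod.family, config.r_fm,
                                     config.r_fm_scope)
            zM[comp] = _draw_pair_component(rng, n, kappa)
            for col, sex in enumerate(GROUP_SEXES[group]):
                modvals[:, col] += mod.paths(sex)[ci] * zM[comp][:, col]
        for col, sex in enumerate(GROUP_SEXES[group]):
            modvals[:, col] += _mean_vec(mod, sex, ages)
        # centered moderator value driving the path functions
        m_c = np.empty_like(modvals)
        for col, sex in enumerate(GROUP_SEXES[group]):
            m_c[:, col] = modvals[:, col] - mod.mean[sex]
        if mt.abs_moderator:
            m_c = np.abs(m_c)
        traitvals = np.zeros((n, 2))
        for ci, comp in enumerate(("A", "DC", "E")):
            kappa = _component_kappa(group, comp, trait.family, config.r_fm,
                                     config.r_fm_scope)
            zU = _draw_pair_component(rng, n, kappa)
            for col in range(2):
                pc = mt.common0[ci] + mt.beta_common[ci] * m_c[:, col]
                pu = mt.unique0[ci] + mt.beta_unique[ci] * m_c[:, col]
                traitvals[:, col] += pc * zM[comp][:, col] + pu * zU[:, col]
        for col, sex in enumerate(GROUP_SEXES[group]):
            traitvals[:, col] += _mean_vec(trait, sex, ages)
        df[trait.name + "_1"], df[trait.name + "_2"] = traitvals[:, 0], traitvals[:, 1]
        df[mod.name + "_1"], df[mod.name + "_2"] = modvals[:, 0], modvals[:, 1]
        frames.append(df)
    return Cohort(pd.concat(frames, ignore_index=True), [trait.name, mod.name])


def simulate_deficits(cohort: Cohort, config: DeficitConfig,
                      seed: int = 0, liability_trait: str = "FI") -> Cohort:
    """Add binary deficit-item columns driven by a latent liability trait.

    Item j of twin i is endorsed when ``loading·z_i + ε_ij`` exceeds its
    threshold, where z is the standardized liability phenotype and the
    thresholds encode per-item endorsement probabilities at median
    liability.  The resulting item-count index is right-skewed in [0, 1].
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    frame = cohort.frame.copy()
    thresholds = -norm.ppf(config.endorse_probs)   # P(endorse | z=0) = q_j
    lam = np.broadcast_to(np.asarray(config.loading, dtype=float),
                          (config.n_items,))
    vals = np.concatenate([
        frame.loc[frame["present1"], liability_trait + "_1"],
        frame.loc[frame["present2"], liability_trait + "_2"]])
    mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals))
    for suf in ("_1", "_2"):
        z = (frame[liability_trait + suf].to_numpy(dtype=float) - mu) / sd
        z = np.nan_to_num(z)
        noise = rng.standard_normal((len(frame), config.n_items))
        items = (lam[None, :] * z[:, None] + noise > thresholds[None, :]).astype(float)
        present = frame[f"present{suf[-1]}"].to_numpy(dtype=bool)
        items[~present] = np.nan
        if config.item_missing_rate > 0:
            blank = rng.random((len(frame), config.n_items)) < config.item_missing_rate
            items[blank] = np.nan
        width = len(str(config.n_items))
        for j in range(config.n_items):
            frame[f"item{j + 1:0{width}d}{suf}"] = items[:, j]
    return Cohort(frame, cohort.phenotype_names)


def inject_missing(cohort: Cohort, singleton_fraction: float = 0.0,
                   item_missing_rate: float = 0.0, seed: int = 0,
                   item_prefix: str = "item") -> Cohort:
    """Randomly demote complete pairs to singletons and blank item cells."""
    if not 0 <= singleton_fraction < 1 or not 0 <= item_missing_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frame = cohort.frame.copy()
    if singleton_fraction > 0:
        complete = (frame["present1"] & frame["present2"]).to_numpy()
        demote = complete & (rng.random(len(frame)) < singleton_fraction)
        drop_first = rng.random(len(frame)) < 0.5
        value_cols1 = [c for c in frame.columns if c.endswith("_1")]
        value_cols2 = [c for c in frame.columns if c.endswith("_2")]
        d1 = demote & drop_first
        d2 = demote & ~drop_first
        frame.loc[d1, "present1"] = False
        frame.loc[d1, value_cols1] = np.nan
        frame.loc[d2, "present2"] = False
        frame.loc[d2, value_cols2] = np.nan
    if item_missing_rate > 0:
        item_cols = [c for c in frame.columns if c.startswith(item_prefix)
                     and (c.endswith("_1") or c.endswith("_2"))]
        for c in item_cols:
            blank = rng.random(len(frame)) < item_missing_rate
            frame.loc[blank, c] = np.nan
    return Cohort(frame, cohort.phenotype_names)
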