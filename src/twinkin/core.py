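"""Univariate twin models: ACE/ADE/AE/E with sex limitation, fitted by FIML.

The classical twin design decomposes phenotypic variance into additive
genetic (A), dominance genetic (D) or common environmental (C), and unique
environmental (E) sources, using the differing genetic resemblance of
monozygotic (MZ) and dizygotic (DZ) co-twins: A correlates 1 in MZ and 1/2
in DZ pairs, D correlates 1 and 1/4, C correlates 1 in both, E is
uncorrelated.  Broad-sense heritability is H = a² + d² (ADE) or a² (ACE/AE)
as a share of total variance.

Sex limitation:

* ``full`` — sex-specific paths, plus a genetic correlation ``r_fm``
  between the genetic factors of opposite-sex (OS) co-twins; r_fm < 1
  indicates qualitatively different genetic sources across sexes.
* ``quantitative`` — sex-specific paths with r_fm pinned at 1 (same genes,
  different magnitudes).
* ``none`` — the standardized broad-sense share H is equated across sexes
  while total variance (and the A/D split) stays sex-specific.

Age enters the means model inside the likelihood (coefficients estimated
jointly), so twin correlations are not inflated by co-twins sharing an age.
Models are parameterized either through non-negative variance shares
("path" mode) or through unbounded variance components ("direct_symmetric"
mode, which admits negative estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_model import Cohort, GROUP_SEXES, ZYGOSITY_GROUPS
from . import likelihood as lk
from .likelihood import FitResult, lrt  # re-exported

__all__ = [
    "ModelSpec", "VarianceComponents", "FitResult", "expected_pair_cov",
    "fiml_loglik", "fit", "direct_symmetric_fit", "profile_ci", "lrt",
    "KAPPA",
]

#: (additive, dominance) cross-twin correlation per zygosity group
KAPPA = {
    "MZM": (1.0, 1.0), "MZF": (1.0, 1.0),
    "DZM": (0.5, 0.25), "DZF": (0.5, 0.25), "DZOS": (0.5, 0.25),
}

_FAMILIES = ("ADE", "ACE", "AE", "E", "saturated")


@dataclass(frozen=True)
class ModelSpec:
    """Which univariate model to fit, on which trait."""

    trait: str = "FI"
    family: str = "ADE"
    sex_limitation: str = "quantitative"   # full | quantitative | none
    r_fm_mode: str | None = None           # estimated | fixed_1 (default by sexlim)
    r_fm_scope: str = "joint"              # joint: r_fm scales A and D OS terms; additive: A only
    parameterization: str = "path"         # path | direct_symmetric
    age_degree: int = 1

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sex_limitation not in ("full", "quantitative", "none"):
            raise ValueError(f"unknown sex_limitation {self.sex_limitation!r}")
        if self.family == "E" and self.sex_limitation == "full":
            raise ValueError("an E-only model has no genetic paths to sex-limit")
        if self.r_fm_mode is None:
            object.__setattr__(
                self, "r_fm_mode",
                "estimated" if self.sex_limitation == "full" else "fixed_1")

    @property
    def dc_label(self) -> str:
        """'d' for ADE, 'c' for ACE (second variance component)."""
        return "c" if self.family == "ACE" else "d"


@dataclass
class VarianceComponents:
    """Standardized variance shares for one sex."""

    a2: float
    dc2: float           # d² (ADE) or c² (ACE); 0 for AE/E
    e2: float
    total_variance: float
    family: str = "ADE"

    @property
    def H(self) -> float:
        """Broad-sense heritability share: a² + d² (ADE) or a² (ACE/AE)."""
        return self.a2 + (self.dc2 if self.family == "ADE" else 0.0)

    def __post_init__(self):
        s = self.a2 + self.dc2 + self.e2
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"standardized shares must sum to 1 (got {s})")


def expected_pair_cov(spec: ModelSpec, group: str, params: dict) -> np.ndarray:
    """Expected 2×2 phenotypic covariance for one zygosity group.

    ``params`` holds path coefficients per sex — ``a_m, d_m (or c_m), e_m,
    a_f, ...`` — plus ``r_fm`` for OS pairs.  Diagonals are the sex-specific
    total variances a²+d²+e²; the off-diagonal applies the kinship weights
    (MZ 1/1, DZ 1/2 and 1/4 for A and D; C fully shared), and for OS pairs
    the genetic term is additionally scaled by r_fm.
    """
    if group not in ZYGOSITY_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    dc = spec.dc_label
    kA, kD = KAPPA[group]

    def paths(sex):
        suf = "_m" if sex == "M" else "_f"
        a = params.get("a" + suf, 0.0)
        d = params.get(dc + suf, 0.0)
        e = params["e" + suf]
        return a, d, e

    s1, s2 = GROUP_SEXES[group]
    a1, d1, e1 = paths(s1)
    a2_, d2_, e2_ = paths(s2)
    v1 = a1 * a1 + d1 * d1 + e1 * e1
    v2 = a2_ * a2_ + d2_ * d2_ + e2_ * e2_
    if spec.family == "ACE":
        gen = kA * a1 * a2_
        shared = d1 * d2_          # C: fully shared in both MZ and DZ
    else:
        gen = kA * a1 * a2_ + kD * d1 * d2_
        shared = 0.0
    if group == "DZOS":
        r_fm = params.get("r_fm", 1.0)
        if spec.r_fm_scope == "joint" or spec.family == "ACE":
            gen = r_fm * gen
        else:  # additive-only scaling
            gen = r_fm * kA * a1 * a2_ + kD * d1 * d2_
    off = gen + shared
    return np.array([[v1, off], [off, v2]])


# ---------------------------------------------------------------------------
# problem construction


class _GroupData:
    __slots__ = ("y", "age_c", "group", "n")

    def __init__(self, y, age_c, group):
        self.y, self.age_c, self.group, self.n = y, age_c, group, len(y)


def _prepare_groups(cohort: Cohort, trait: str):
    """Per-group (n,2) phenotype arrays with nan for absent twins, centered age."""
    frame = cohort.frame
    ages = frame["age"].to_numpy(dtype=float)
    present = np.column_stack([frame["present1"], frame["present2"]]).astype(bool)
    center = float(np.mean(np.repeat(ages, present.sum(axis=1))))
    groups = {}
    for g in ZYGOSITY_GROUPS:
        mask = (frame["zygosity_group"] == g).to_numpy()
        if not mask.any():
            continue
        y = frame.loc[mask, [trait + "_1", trait + "_2"]].to_numpy(dtype=float).copy()
        y[~present[mask]] = np.nan
        keep = ~np.isnan(y).all(axis=1)
        groups[g] = _GroupData(y[keep], ages[mask][keep] - center, g)
    if not groups:
        raise ValueError(f"cohort has no observations for trait {trait!r}")
    return groups, center


class UnivariateProblem:
    """Maps a raw parameter vector to the FIML −2 log L of a univariate model."""

    def __init__(self, spec: ModelSpec, cohort: Cohort):
        self.spec = spec
        self.groups, self.age_center = _prepare_groups(cohort, spec.trait)
        self.sexes = sorted({s for g in self.groups for s in GROUP_SEXES[g]})
        self._build_layout()
        self._starts_from_moments()

    # -- parameter layout ---------------------------------------------------
    def _build_layout(self):
        spec = self.spec
        names, bounds = [], []
        deg = spec.age_degree
        if spec.family == "saturated":
            for g in self.groups:
                if g == "DZOS":
                    for sex in ("m", "f"):
                        names += [f"b0_{g}_{sex}"] + [f"bage{k}_{g}_{sex}" for k in range(1, deg + 1)]
                        bounds += [(None, None)] * (1 + deg)
                        names += [f"logV_{g}_{sex}"]
                        bounds += [(-46.0, 46.0)]
                    names += [f"r_{g}"]
                    bounds += [(-0.999, 0.999)]
                else:
                    names += [f"b0_{g}"] + [f"bage{k}_{g}" for k in range(1, deg + 1)]
                    bounds += [(None, None)] * (1 + deg)
                    names += [f"logV_{g}", f"r_{g}"]
                    bounds += [(-46.0, 46.0), (-0.999, 0.999)]
            self.param_names, self.bounds = names, bounds
            return
        for s in self.sexes:
            suf = s.lower()
            names += [f"b0_{suf}"] + [f"bage{k}_{suf}" for k in range(1, deg + 1)]
            bounds += [(None, None)] * (1 + deg)
        if spec.parameterization == "direct_symmetric":
            comp = {"ADE": ("VA", "VD"), "ACE": ("VA", "VC"),
                    "AE": ("VA",), "E": ()}[spec.family]
            for s in self.sexes:
                suf = s.lower()
                for cname in comp + ("VE",):
                    names.append(f"{cname}_{suf}")
                    bounds.append((None, None))
        else:
            shared_h = spec.sex_limitation == "none" and len(self.sexes) == 2
            for s in self.sexes:
                suf = s.lower()
                names.append(f"logV_{suf}")
                bounds.append((-46.0, 46.0))
            if spec.family != "E":
                if shared_h:
                    names.append("h")
                    bounds.append((0.0, 1.0))
                else:
                    for s in self.sexes:
                        names.append(f"h_{s.lower()}")
                        bounds.append((0.0, 1.0))
            if spec.family in ("ADE", "ACE"):
                sub = "g" if spec.family == "ADE" else "u"
                for s in self.sexes:
                    names.append(f"{sub}_{s.lower()}")
                    bounds.append((0.0, 1.0))
        if ("DZOS" in self.groups and spec.family != "E"
                and spec.r_fm_mode == "estimated"):
            names.append("r_fm")
            bounds.append((-1.0, 1.0))
        self.param_names, self.bounds = names, bounds

    def _idx(self, name):
        return self.param_names.index(name)

    # -- starting values ----------------------------------------------------
    def _moment_summaries(self):
        """Pooled per-sex sample moments for start values."""
        out = {}
        for s in self.sexes:
            ys, ages = [], []
            for g, gd in self.groups.items():
                for col, sex in zip((0, 1), GROUP_SEXES[g]):
                    if sex == s:
                        ok = ~np.isnan(gd.y[:, col])
                        ys.append(gd.y[ok, col])
                        ages.append(gd.age_c[ok])
            y = np.concatenate(ys)
            a = np.concatenate(ages)
            deg = self.spec.age_degree
            X = np.column_stack([np.ones_like(a)] + [a ** k for k in range(1, deg + 1)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid_var = float(np.var(y - X @ beta))
            out[s] = {"beta": beta, "var": max(resid_var, 1e-12)}
        # crude intraclass correlations per group for Falconer-style starts
        rs = {}
        for g, gd in self.groups.items():
            both = ~np.isnan(gd.y).any(axis=1)
            if both.sum() > 2:
                rs[g] = float(np.corrcoef(gd.y[both, 0], gd.y[both, 1])[0, 1])
        out["icc"] = rs
        return out

    def _starts_from_moments(self):
        mom = self._moment_summaries()
        spec = self.spec
        x0 = np.zeros(len(self.param_names))
        deg = spec.age_degree
        if spec.family == "saturated":
            for g, gd in self.groups.items():
                if g == "DZOS":
                    for col, sex in ((0, "m"), (1, "f")):
                        m = mom[GROUP_SEXES[g][col]]
                        x0[self._idx(f"b0_{g}_{sex}")] = m["beta"][0]
                        for k in range(1, deg + 1):
                            x0[self._idx(f"bage{k}_{g}_{sex}")] = m["beta"][k]
                        x0[self._idx(f"logV_{g}_{sex}")] = np.log(m["var"])
                else:
                    m = mom[GROUP_SEXES[g][0]]
                    x0[self._idx(f"b0_{g}")] = m["beta"][0]
                    for k in range(1, deg + 1):
                        x0[self._idx(f"bage{k}_{g}")] = m["beta"][k]
                    x0[self._idx(f"logV_{g}")] = np.log(m["var"])
                x0[self._idx(f"r_{g}")] = np.clip(mom["icc"].get(g, 0.2), -0.9, 0.9)
            self.x0 = x0
            return
        icc = mom["icc"]
        for s in self.sexes:
            suf = s.lower()
            m = mom[s]
            x0[self._idx(f"b0_{suf}")] = m["beta"][0]
            for k in range(1, deg + 1):
                x0[self._idx(f"bage{k}_{suf}")] = m["beta"][k]
            rmz = icc.get("MZM" if s == "M" else "MZF", 0.4)
            rdz = icc.get("DZM" if s == "M" else "DZF", 0.2)
            if spec.family == "ACE":
                a2 = np.clip(2 * (rmz - rdz), 0.0, 0.95)
                c2 = np.clip(2 * rdz - rmz, 0.0, 0.95 - a2)
                h, sub = a2, (c2 / max(1e-6, 1 - a2))
            else:
                a2 = np.clip(4 * rdz - rmz, 0.0, 0.95)
                d2 = np.clip(2 * rmz - 4 * rdz, 0.0, 0.95 - a2)
                if spec.family == "AE":
                    h, sub = np.clip(rmz, 0.0, 0.95), None
                else:
                    h = np.clip(a2 + d2, 0.0, 0.95)
                    sub = a2 / max(h, 1e-6)
            if spec.parameterization == "direct_symmetric":
                V = m["var"]
                comp = {"ADE": ("VA", "VD"), "ACE": ("VA", "VC"),
                        "AE": ("VA",), "E": ()}[spec.family]
                split = {"VA": a2, "VD": h - a2 if spec.family == "ADE" else 0.0,
                         "VC": np.clip(2 * rdz - rmz, 0, 1) if spec.family == "ACE" else 0.0}
                used = 0.0
                for cname in comp:
                    x0[self._idx(f"{cname}_{suf}")] = split[cname] * V
                    used += split[cname]
                x0[self._idx(f"VE_{suf}")] = max(1e-6, (1 - used)) * V
            else:
                x0[self._idx(f"logV_{suf}")] = np.log(m["var"])
                if spec.family != "E":
                    hname = "h" if "h" in self.param_names else f"h_{suf}"
                    x0[self._idx(hname)] = np.clip(h, 0.02, 0.95)
                if spec.family in ("ADE", "ACE"):
                    key = ("g" if spec.family == "ADE" else "u") + f"_{suf}"
                    x0[self._idx(key)] = np.clip(sub, 0.05, 0.95)
        if "r_fm" in self.param_names:
            x0[self._idx("r_fm")] = 0.8
        self.x0 = x0

    # -- evaluation ---------------------------------------------------------
    def _paths_for(self, x, sex):
        """(a, d_or_c, e) path coefficients for one sex from the raw vector."""
        spec = self.spec
        suf = sex.lower()
        if spec.parameterization == "direct_symmetric":
            comp = {"ADE": ("VA", "VD"), "ACE": ("VA", "VC"),
                    "AE": ("VA",), "E": ()}[spec.family]
            VA = x[self._idx(f"VA_{suf}")] if "VA" in comp else 0.0
            VD = 0.0
            if "VD" in comp:
                VD = x[self._idx(f"VD_{suf}")]
            if "VC" in comp:
                VD = x[self._idx(f"VC_{suf}")]
            VE = x[self._idx(f"VE_{suf}")]
            return ("direct", VA, VD, VE)
        V = float(np.exp(x[self._idx(f"logV_{suf}")]))
        if spec.family == "E":
            return ("path", 0.0, 0.0, np.sqrt(V))
        h = x[self._idx("h" if "h" in self.param_names else f"h_{suf}")]
        if spec.family == "AE":
            a2, dc2 = h * V, 0.0
        elif spec.family == "ADE":
            g = x[self._idx(f"g_{suf}")]
            a2, dc2 = h * g * V, h * (1 - g) * V
        else:  # ACE
            u = x[self._idx(f"u_{suf}")]
            a2, dc2 = h * V, (1 - h) * u * V
        e2 = V - a2 - dc2
        return ("path", np.sqrt(max(a2, 0)), np.sqrt(max(dc2, 0)), np.sqrt(max(e2, 1e-300)))

    def _group_sigma(self, x, group):
        spec = self.spec
        kA, kD = KAPPA[group]
        s1, s2 = GROUP_SEXES[group]
        p1, p2 = self._paths_for(x, s1), self._paths_for(x, s2)
        r_fm = 1.0
        if group == "DZOS":
            if "r_fm" in self.param_names:
                r_fm = x[self._idx("r_fm")]
        if p1[0] == "direct":
            _, VA1, VD1, VE1 = p1
            _, VA2, VD2, VE2 = p2
            v1, v2 = VA1 + VD1 + VE1, VA2 + VD2 + VE2
            if s1 == s2:
                if spec.family == "ACE":
                    off = kA * VA1 + VD1
                else:
                    off = kA * VA1 + kD * VD1
            else:
                if VA1 * VA2 < 0 or VD1 * VD2 < 0:
                    return None  # cross-sex covariance undefined; reject point
                gA, gD = np.sqrt(VA1 * VA2), np.sqrt(VD1 * VD2)
                if spec.family == "ACE":
                    off = r_fm * kA * gA + gD
                elif spec.r_fm_scope == "joint":
                    off = r_fm * (kA * gA + kD * gD)
                else:
                    off = r_fm * kA * gA + kD * gD
            return np.array([[v1, off], [off, v2]])
        _, a1, d1, e1 = p1
        _, a2_, d2_, e2_ = p2
        v1 = a1 ** 2 + d1 ** 2 + e1 ** 2
        v2 = a2_ ** 2 + d2_ ** 2 + e2_ ** 2
        if spec.family == "ACE":
            gen, shared = kA * a1 * a2_, d1 * d2_
        else:
            gen, shared = kA * a1 * a2_ + kD * d1 * d2_, 0.0
        if group == "DZOS":
            if spec.family == "ACE" or spec.r_fm_scope == "joint":
                gen *= r_fm
            else:
                gen = r_fm * kA * a1 * a2_ + kD * d1 * d2_
        return np.array([[v1, gen + shared], [gen + shared, v2]])

    def _mu_for_group(self, x, group, gd):
        deg = self.spec.age_degree
        if self.spec.family == "saturated":
            if group == "DZOS":
                cols = []
                for sex in ("m", "f"):
                    b = x[self._idx(f"b0_{group}_{sex}")]
                    mu = np.full(gd.n, b)
                    for k in range(1, deg + 1):
                        mu = mu + x[self._idx(f"bage{k}_{group}_{sex}")] * gd.age_c ** k
                    cols.append(mu)
                return np.column_stack(cols)
            b = x[self._idx(f"b0_{group}")]
            mu = np.full(gd.n, b)
            for k in range(1, deg + 1):
                mu = mu + x[self._idx(f"bage{k}_{group}")] * gd.age_c ** k
            return np.column_stack([mu, mu])
        cols = []
        for sex in GROUP_SEXES[group]:
            suf = sex.lower()
            mu = np.full(gd.n, x[self._idx(f"b0_{suf}")])
            for k in range(1, deg + 1):
                mu = mu + x[self._idx(f"bage{k}_{suf}")] * gd.age_c ** k
            cols.append(mu)
        return np.column_stack(cols)

    def _saturated_sigma(self, x, group):
        if group == "DZOS":
            v1 = np.exp(x[self._idx(f"logV_{group}_m")])
            v2 = np.exp(x[self._idx(f"logV_{group}_f")])
        else:
            v1 = v2 = np.exp(x[self._idx(f"logV_{group}")])
        r = x[self._idx(f"r_{group}")]
        off = r * np.sqrt(v1 * v2)
        return np.array([[v1, off], [off, v2]])

    def objective(self, x) -> float:
        total = 0.0
        for g, gd in self.groups.items():
            sigma = (self._saturated_sigma(x, g) if self.spec.family == "saturated"
                     else self._group_sigma(x, g))
            if sigma is None:
                return lk.REJECT
            mu = self._mu_for_group(x, g, gd)
            val = lk.mvn_m2ll_pattern(gd.y, mu, sigma)
            if val >= lk.REJECT:
                return lk.REJECT
            total += val
        return total

    # -- reporting ----------------------------------------------------------
    def estimates(self, x) -> dict:
        spec = self.spec
        est = {}
        if spec.family == "saturated":
            for g in self.groups:
                est[f"r_{g}"] = float(x[self._idx(f"r_{g}")])
            est["age_center"] = self.age_center
            return est
        for s in self.sexes:
            suf = s.lower()
            p = self._paths_for(x, s)
            if p[0] == "direct":
                _, VA, VD, VE = p
                V = VA + VD + VE
                a2, dc2, e2 = VA / V, VD / V, VE / V
            else:
                _, a, d, e = p
                V = a * a + d * d + e * e
                a2, dc2, e2 = a * a / V, d * d / V, e * e / V
            dc = spec.dc_label
            est[f"V_{suf}"] = float(V)
            est[f"a2_{suf}"] = float(a2)
            est[f"{dc}2_{suf}"] = float(dc2)
            est[f"e2_{suf}"] = float(e2)
            est[f"H_{suf}"] = float(a2 + dc2) if spec.family == "ADE" else float(a2)
            est[f"b0_{suf}"] = float(x[self._idx(f"b0_{suf}")])
            for k in range(1, spec.age_degree + 1):
                est[f"bage{k}_{suf}"] = float(x[self._idx(f"bage{k}_{suf}")])
        if "r_fm" in self.param_names:
            est["r_fm"] = float(x[self._idx("r_fm")])
        elif "DZOS" in self.groups and spec.family != "E":
            est["r_fm"] = 1.0
        est["age_center"] = self.age_center
        return est

    def components(self, x) -> dict:
        """Per-sex VarianceComponents from a raw vector."""
        est = self.estimates(x)
        out = {}
        for s in self.sexes:
            suf = s.lower()
            out[s] = VarianceComponents(
                a2=est[f"a2_{suf}"], dc2=est[f"{spec_dc(self.spec)}2_{suf}"],
                e2=est[f"e2_{suf}"], total_variance=est[f"V_{suf}"],
                family=self.spec.family)
        return out


def spec_dc(spec: ModelSpec) -> str:
    return spec.dc_label


def fiml_loglik(spec: ModelSpec, cohort: Cohort, params) -> float:
    """−2 log-likelihood of a cohort under a model at given parameter values.

    ``params`` is either a raw vector (in the problem's parameter order) or
    a dict keyed by parameter name.
    """
    prob = UnivariateProblem(spec, cohort)
    if isinstance(params, dict):
        x = prob.x0.copy()
        for k, v in params.items():
            x[prob._idx(k)] = v
    else:
        x = np.asarray(params, dtype=float)
    return prob.objective(x)


def fit(spec: ModelSpec, cohort: Cohort, n_restarts: int = 3, seed: int = 0,
        jitter: float = 0.1, tol: float = 1e-9) -> FitResult:
    """Fit a univariate twin model by FIML with multistart quasi-Newton.

    ``tol`` is the optimizer's relative ftol; tighten it (e.g. 1e-13) when
    weakly identified directions such as the A/D split must be resolved
    precisely.
    """
    prob = UnivariateProblem(spec, cohort)
    best, agree = lk.multistart_minimize(prob.objective, prob.x0, prob.bounds,
                                         n_restarts=n_restarts, seed=seed,
                                         jitter=jitter, tol=tol)
    gnorm = float(np.abs(best.jac).max())
    converged = bool(best.success) and best.fun < lk.REJECT / 2
    if not converged:
        warnings.warn(f"fit did not converge cleanly (gradient norm {gnorm:.3g})")
    fr = FitResult(
        estimates=prob.estimates(best.x), minus2ll=float(best.fun),
        n_params=len(prob.param_names), converged=converged,
        gradient_norm=gnorm, params=np.asarray(best.x),
        param_names=list(prob.param_names), spec=spec,
        n_restarts_agreeing=agree,
        _objective=prob.objective, _bounds=prob.bounds,
        _estimator=prob.estimates,
    )
    return fr


def direct_symmetric_fit(spec: ModelSpec, cohort: Cohort, n_restarts: int = 3,
                         seed: int = 0, tol: float = 1e-9) -> FitResult:
    """Fit with variance components parameterized directly (may go negative)."""
    return fit(replace(spec, parameterization="direct_symmetric"), cohort,
               n_restarts=n_restarts, seed=seed, tol=tol)


_ALIASES = {"H_m": "h_m", "H_f": "h_f", "H": "h"}


def profile_ci(fitres: FitResult, param: str, level: float = 0.95):
    """Profile-likelihood confidence interval for a fitted parameter.

    ``param`` may be a raw parameter name or one of the share aliases
    (``H_m``/``H_f``/``H``).  Endpoints that run into the parameter-space
    boundary are reported at the boundary (e.g. a zero lower limit for a
    variance share).
    """
    if fitres._objective is None:
        raise ValueError("fit result carries no objective; refit with fit()")
    name = _ALIASES.get(param, param)
    if name not in fitres.param_names:
        raise KeyError(f"no raw parameter {param!r}; available: {fitres.param_names}")
    idx = fitres.param_names.index(name)
    lo, hi = lk.profile_ci(fitres._objective, fitres.params, fitres.minus2ll,
                           idx, fitres._bounds, level=level)
    fitres.ci[param] = (float(lo), float(hi))
    return float(lo), float(hi)
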