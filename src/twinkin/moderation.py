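"""Gene-environment moderation models.

Path coefficients of a trait are allowed to vary linearly with a measured
moderator (each twin's own value): path(m) = path0 + β·m.  Two model
families are provided:

* **full bivariate moderation** — the moderator is modelled jointly with
  the trait; the trait decomposes into components *common* with the
  moderator and components *unique* to it, and both sets of paths may be
  moderated.  This accommodates moderation of the trait-moderator
  covariance as well as of the unique variance.
* **extended univariate moderation** — trait paths are moderated while
  both twins' moderator values enter the means model as main effects; the
  co-twin main effect guards against covariance moderation masquerading as
  unique-variance moderation.  Appropriate when covariance moderation is
  absent.

A likelihood-ratio ladder (no moderation → unique-path moderation →
unique+common moderation) decides which family a given trait-moderator
pair warrants.  Moderation is examined separately by sex on same-sex
pairs; variance is linear in m only through the paths, so U-shaped
variance profiles emerge naturally from squaring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import Cohort
from . import likelihood as lk
from .likelihood import FitResult

_SEX_GROUPS = {"M": ("MZM", "DZM"), "F": ("MZF", "DZF")}
_KAPPA = {"MZ": (1.0, 1.0), "DZ": (0.5, 0.25)}
_COMP = {"ADE": ("a", "d", "e"), "ACE": ("a", "c", "e"), "AE": ("a", "e")}


@dataclass
class ModerationSpec:
    """Which paths are moderated, and where the variance curves are read."""

    trait: str
    moderator: str
    family: str = "ADE"
    moderated_paths: tuple = ("a_unique", "d_unique", "e_unique")
    grid: np.ndarray | None = None
    grid_points: int = 15


@dataclass
class ModeratedVariance:
    """Variance-component curves over a moderator grid (one sex).

    ``grid`` is on the original moderator scale; absolute component
    variances, total, and proportional curves (H(m), E(m)) are per grid
    point.  Proportions sum to 1 at every point.
    """

    grid: np.ndarray
    abs_A: np.ndarray
    abs_DC: np.ndarray
    abs_E: np.ndarray
    family: str = "ADE"
    abs_common: np.ndarray | None = None   # common-with-moderator part of total
    abs_unique: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.abs_A + self.abs_DC + self.abs_E

    @property
    def prop_H(self) -> np.ndarray:
        gen = self.abs_A + (self.abs_DC if self.family == "ADE" else 0.0)
        return gen / self.total

    @property
    def prop_E(self) -> np.ndarray:
        return self.abs_E / self.total


@dataclass
class ModerationFit:
    """Per-sex fit results and variance curves for a moderation model."""

    kind: str                          # "full_bivariate" | "extended_univariate"
    spec: ModerationSpec
    fits: dict                         # sex -> FitResult
    curves: dict                       # sex -> ModeratedVariance

    @property
    def minus2ll(self) -> float:
        return float(sum(f.minus2ll for f in self.fits.values()))

    @property
    def n_params(self) -> int:
        return int(sum(f.n_params for f in self.fits.values()))

    @property
    def aic(self) -> float:
        return self.minus2ll + 2 * self.n_params


def _sex_data(cohort: Cohort, trait: str, moderator: str | None, sex: str):
    """Per-zygosity arrays for one sex: complete pairs and singletons.

    Complete pairs need the trait and (when a moderator is used) both
    twins' moderator values; pairs lacking a co-twin moderator are
    downgraded to two singletons with a warning.
    """
    frame = cohort.frame
    out = {}
    ages_all = []
    for zyg, g in zip(("MZ", "DZ"), _SEX_GROUPS[sex]):
        mask = (frame["zygosity_group"] == g).to_numpy()
        if not mask.any():
            continue
        sub = frame.loc[mask]
        yt = sub[[trait + "_1", trait + "_2"]].to_numpy(dtype=float).copy()
        p = np.column_stack([sub["present1"], sub["present2"]]).astype(bool)
        yt[~p] = np.nan
        ages = sub["age"].to_numpy(dtype=float)
        if moderator is None:
            ym = np.full_like(yt, np.nan)
        else:
            ym = sub[[moderator + "_1", moderator + "_2"]].to_numpy(dtype=float).copy()
            ym[~p] = np.nan
        ok_t = ~np.isnan(yt)
        ok_m = ~np.isnan(ym)
        pair_ok = ok_t.all(axis=1) & ok_m.all(axis=1)
        single_rows = []
        n_downgraded = 0
        for col in (0, 1):
            # twins usable only marginally: observed own trait+moderator in
            # a pair that is not fully observed
            solo = ok_t[:, col] & ok_m[:, col] & ~pair_ok
            n_downgraded += int((solo & ok_t[:, 1 - col] & p[:, 1 - col]).sum())
            single_rows.append((yt[solo, col], ym[solo, col], ages[solo]))
        if n_downgraded:
            warnings.warn(f"{g}: {n_downgraded} pairs downgraded to singletons "
                          "(missing co-twin moderator or trait)")
        out[zyg] = {
            "y": yt[pair_ok], "m": ym[pair_ok], "age": ages[pair_ok],
            "solo_y": np.concatenate([s[0] for s in single_rows]),
            "solo_m": np.concatenate([s[1] for s in single_rows]),
            "solo_age": np.concatenate([s[2] for s in single_rows]),
        }
        ages_all.append(ages)
        if moderator is not None:
            # fully-missing moderator rows are silently unusable
            pass
    if not out:
        raise ValueError(f"no same-sex pairs for sex {sex!r}")
    return out


def _center(values):
    vals = np.concatenate(values)
    return float(np.nanmean(vals))


def _default_grid(mvals: np.ndarray, points: int) -> np.ndarray:
    lo, hi = np.nanpercentile(mvals, [1, 99])
    return np.linspace(lo, hi, points)


class _ExtendedUnivariateProblem:
    """Extended univariate moderation model for one sex."""

    def __init__(self, cohort, spec: ModerationSpec, sex: str):
        self.spec = spec
        self.family = spec.family
        self.data = _sex_data(cohort, spec.trait, spec.moderator, sex)
        all_m = np.concatenate([np.ravel(d["m"]) for d in self.data.values()]
                               + [d["solo_m"] for d in self.data.values()])
        all_age = np.concatenate([d["age"] for d in self.data.values()]
                                 + [d["solo_age"] for d in self.data.values()])
        self.m_center = float(np.nanmean(all_m))
        self.age_center = float(np.nanmean(all_age))
        self.m_range = (float(np.nanmin(all_m)), float(np.nanmax(all_m)))
        self._all_m = all_m
        self._layout()
        self._starts()

    def _layout(self):
        comps = _COMP[self.family]
        names = ["b0", "bage", "bm_self", "bm_cotwin"]
        bounds = [(None, None)] * 4
        for c in comps:
            names.append(f"{c}0")
            bounds.append((None, None))
        self.beta_names = []
        for c in comps:
            key = f"{c}_unique" if self.family != "ACE" else f"{c}_unique"
            if f"{c}_unique" in self.spec.moderated_paths:
                names.append(f"beta_{c}")
                bounds.append((None, None))
                self.beta_names.append(f"beta_{c}")
        self.param_names, self.bounds = names, bounds

    def _idx(self, n):
        return self.param_names.index(n)

    def _starts(self):
        x0 = np.zeros(len(self.param_names))
        ys, ms, ages = [], [], []
        for d in self.data.values():
            ys += [d["y"][:, 0], d["y"][:, 1], d["solo_y"]]
            ms += [d["m"][:, 0], d["m"][:, 1], d["solo_m"]]
            ages += [d["age"], d["age"], d["solo_age"]]
        y = np.concatenate(ys)
        m = np.concatenate(ms) - self.m_center
        a = np.concatenate(ages) - self.age_center
        X = np.column_stack([np.ones_like(y), a, m])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        x0[self._idx("b0")], x0[self._idx("bage")] = beta[0], beta[1]
        x0[self._idx("bm_self")] = beta[2]
        resid_var = max(float(np.var(y - X @ beta)), 1e-12)
        rmz = rdz = 0.2
        for z, d in self.data.items():
            if len(d["y"]) > 3:
                r = float(np.corrcoef(d["y"][:, 0], d["y"][:, 1])[0, 1])
                if z == "MZ":
                    rmz = r
                else:
                    rdz = r
        comps = _COMP[self.family]
        if self.family == "ACE":
            a2 = np.clip(2 * (rmz - rdz), 0.02, 0.9)
            dc2 = np.clip(2 * rdz - rmz, 0.0, 0.9 - a2)
        else:
            a2 = np.clip(4 * rdz - rmz, 0.02, 0.9)
            dc2 = np.clip(2 * rmz - 4 * rdz, 0.0, 0.9 - a2)
            if self.family == "AE":
                a2, dc2 = np.clip(rmz, 0.02, 0.9), 0.0
        e2 = max(1 - a2 - dc2, 0.05)
        scale = np.sqrt(resid_var / (a2 + dc2 + e2))
        vals = {"a": np.sqrt(a2), "e": np.sqrt(e2)}
        if len(comps) == 3:
            vals[comps[1]] = np.sqrt(dc2)
        for c in comps:
            x0[self._idx(f"{c}0")] = vals.get(c, 0.1) * scale
        self.x0 = x0

    def _path_values(self, x, m_c):
        comps = _COMP[self.family]
        m_c = np.asarray(m_c, dtype=float)
        out = {}
        for c in comps:
            p = x[self._idx(f"{c}0")] + np.zeros_like(m_c)
            if f"beta_{c}" in self.param_names:
                p = p + x[self._idx(f"beta_{c}")] * m_c
            out[c] = p
        return out

    def objective(self, x) -> float:
        total = 0.0
        for zyg, d in self.data.items():
            kA, kD = _KAPPA[zyg]
            m_c = d["m"] - self.m_center
            a_c = d["age"] - self.age_center
            p1 = self._path_values(x, m_c[:, 0])
            p2 = self._path_values(x, m_c[:, 1])
            v1 = sum(p1[c] ** 2 for c in p1)
            v2 = sum(p2[c] ** 2 for c in p2)
            cov = kA * p1["a"] * p2["a"]
            if "d" in p1:
                cov = cov + kD * p1["d"] * p2["d"]
            if "c" in p1:
                cov = cov + p1["c"] * p2["c"]
            n = len(v1)
            sig = np.empty((n, 2, 2))
            sig[:, 0, 0], sig[:, 1, 1] = v1, v2
            sig[:, 0, 1] = sig[:, 1, 0] = cov
            mu = np.empty((n, 2))
            base = x[self._idx("b0")] + x[self._idx("bage")] * a_c
            mu[:, 0] = base + x[self._idx("bm_self")] * m_c[:, 0] \
                + x[self._idx("bm_cotwin")] * m_c[:, 1]
            mu[:, 1] = base + x[self._idx("bm_self")] * m_c[:, 1] \
                + x[self._idx("bm_cotwin")] * m_c[:, 0]
            val = lk.mvn_m2ll_batched(d["y"], mu, sig)
            if val >= lk.REJECT:
                return lk.REJECT
            total += val
            if len(d["solo_y"]):
                sm = d["solo_m"] - self.m_center
                ps = self._path_values(x, sm)
                v = sum(ps[c] ** 2 for c in ps)
                mus = (x[self._idx("b0")]
                       + x[self._idx("bage")] * (d["solo_age"] - self.age_center)
                       + x[self._idx("bm_self")] * sm)
                if np.any(v <= 0):
                    return lk.REJECT
                total += float(np.sum(np.log(2 * np.pi * v)
                                      + (d["solo_y"] - mus) ** 2 / v))
        return total

    def curves(self, x, grid) -> ModeratedVariance:
        m_c = grid - self.m_center
        p = self._path_values(x, m_c)
        zeros = np.zeros_like(m_c)
        dc = p.get("d", p.get("c", zeros))
        return ModeratedVariance(
            grid=np.asarray(grid), abs_A=np.asarray(p["a"] ** 2 + zeros),
            abs_DC=np.asarray(dc ** 2 + zeros), abs_E=np.asarray(p["e"] ** 2 + zeros),
            family="ACE" if self.family == "ACE" else "ADE")


class _FullBivariateProblem:
    """Full bivariate moderation model (trait + moderator jointly) for one sex.

    The moderator has unmoderated paths; the trait splits into paths common
    with the moderator's latent factors and paths unique to the trait,
    each optionally moderated by the twin's own moderator value.
    """

    def __init__(self, cohort, spec: ModerationSpec, sex: str):
        self.spec = spec
        self.family = spec.family
        self.data = _sex_data(cohort, spec.trait, spec.moderator, sex)
        all_m = np.concatenate([np.ravel(d["m"]) for d in self.data.values()]
                               + [d["solo_m"] for d in self.data.values()])
        all_age = np.concatenate([d["age"] for d in self.data.values()]
                                 + [d["solo_age"] for d in self.data.values()])
        self.m_center = float(np.nanmean(all_m))
        self.age_center = float(np.nanmean(all_age))
        self.m_range = (float(np.nanmin(all_m)), float(np.nanmax(all_m)))
        self._all_m = all_m
        self._layout()
        self._starts()

    def _layout(self):
        comps = _COMP[self.family]
        names = ["b0_t", "bage_t", "b0_m", "bage_m"]
        bounds = [(None, None)] * 4
        for c in comps:                      # moderator's own paths
            names.append(f"{c}M")
            bounds.append((0.0 if c == "e" else None, None))
        for c in comps:                      # common-path intercepts
            names.append(f"{c}C0")
            bounds.append((None, None))
        for c in comps:                      # unique-path intercepts
            names.append(f"{c}U0")
            bounds.append((None, None))
        for c in comps:
            if f"{c}_common" in self.spec.moderated_paths:
                names.append(f"beta_{c}C")
                bounds.append((None, None))
        for c in comps:
            if f"{c}_unique" in self.spec.moderated_paths:
                names.append(f"beta_{c}U")
                bounds.append((None, None))
        self.param_names, self.bounds = names, bounds

    def _idx(self, n):
        return self.param_names.index(n)

    def _starts(self):
        x0 = np.zeros(len(self.param_names))
        ys, ms, ages = [], [], []
        for d in self.data.values():
            ys += [d["y"][:, 0], d["y"][:, 1], d["solo_y"]]
            ms += [d["m"][:, 0], d["m"][:, 1], d["solo_m"]]
            ages += [d["age"], d["age"], d["solo_age"]]
        y, m = np.concatenate(ys), np.concatenate(ms)
        a = np.concatenate(ages) - self.age_center
        for (vals, b0k, bagek) in ((y, "b0_t", "bage_t"), (m, "b0_m", "bage_m")):
            X = np.column_stack([np.ones_like(vals), a])
            beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
            x0[self._idx(b0k)], x0[self._idx(bagek)] = beta[0], beta[1]
        def falconer(col):
            rmz = rdz = 0.2
            vres = 1.0
            for z, d in self.data.items():
                yy = d["y"] if col == "t" else d["m"]
                if len(yy) > 3:
                    r = float(np.corrcoef(yy[:, 0], yy[:, 1])[0, 1])
                    rmz, rdz = (r, rdz) if z == "MZ" else (rmz, r)
                    vres = float(np.var(yy))
            if self.family == "ACE":
                a2 = np.clip(2 * (rmz - rdz), 0.02, 0.9)
                dc2 = np.clip(2 * rdz - rmz, 0.0, 0.9 - a2)
            elif self.family == "ADE":
                a2 = np.clip(4 * rdz - rmz, 0.02, 0.9)
                dc2 = np.clip(2 * rmz - 4 * rdz, 0.0, 0.9 - a2)
            else:
                a2, dc2 = np.clip(rmz, 0.02, 0.9), 0.0
            e2 = max(1 - a2 - dc2, 0.05)
            return a2, dc2, e2, vres
        comps = _COMP[self.family]
        a2, dc2, e2, vm = falconer("m")
        sm = np.sqrt(vm)
        vals = {"a": np.sqrt(a2) * sm, "e": np.sqrt(e2) * sm}
        if len(comps) == 3:
            vals[comps[1]] = np.sqrt(dc2) * sm
        for c in comps:
            x0[self._idx(f"{c}M")] = vals.get(c, 0.1)
        a2, dc2, e2, vt = falconer("t")
        st = np.sqrt(vt)
        # split trait paths: a modest common loading, the rest unique
        rp = 0.2
        valsU = {"a": np.sqrt(a2) * st, "e": np.sqrt(e2) * st}
        if len(comps) == 3:
            valsU[comps[1]] = np.sqrt(dc2) * st
        for c in comps:
            x0[self._idx(f"{c}C0")] = rp * valsU.get(c, 0.1)
            x0[self._idx(f"{c}U0")] = np.sqrt(max(1 - rp ** 2, 0.1)) * valsU.get(c, 0.1)
        self.x0 = x0

    def _paths(self, x, m_c):
        comps = _COMP[self.family]
        common, unique = {}, {}
        for c in comps:
            pc = x[self._idx(f"{c}C0")] + (
                x[self._idx(f"beta_{c}C")] * m_c
                if f"beta_{c}C" in self.param_names else 0.0)
            pu = x[self._idx(f"{c}U0")] + (
                x[self._idx(f"beta_{c}U")] * m_c
                if f"beta_{c}U" in self.param_names else 0.0)
            common[c], unique[c] = pc, pu
        return common, unique

    def _kappas(self, zyg):
        kA, kD = _KAPPA[zyg]
        if self.family == "ACE":
            return {"a": kA, "c": 1.0, "e": 0.0}
        if self.family == "AE":
            return {"a": kA, "e": 0.0}
        return {"a": kA, "d": kD, "e": 0.0}

    def objective(self, x) -> float:
        comps = _COMP[self.family]
        pM = {c: x[self._idx(f"{c}M")] for c in comps}
        vM = sum(pM[c] ** 2 for c in comps)
        if vM <= 0:
            return lk.REJECT
        total = 0.0
        for zyg, d in self.data.items():
            kap = self._kappas(zyg)
            m_c = d["m"] - self.m_center
            a_c = d["age"] - self.age_center
            c1, u1 = self._paths(x, m_c[:, 0])
            c2, u2 = self._paths(x, m_c[:, 1])
            n = len(a_c)
            sig = np.empty((n, 4, 4))        # order (M1, y1, M2, y2)
            covMM = sum(kap[c] * pM[c] ** 2 for c in comps)
            sig[:, 0, 0] = vM
            sig[:, 2, 2] = vM
            sig[:, 0, 2] = sig[:, 2, 0] = covMM
            v1 = sum(c1[c] ** 2 + u1[c] ** 2 for c in comps)
            v2 = sum(c2[c] ** 2 + u2[c] ** 2 for c in comps)
            sig[:, 1, 1], sig[:, 3, 3] = v1, v2
            sig[:, 0, 1] = sig[:, 1, 0] = sum(pM[c] * c1[c] for c in comps)
            sig[:, 2, 3] = sig[:, 3, 2] = sum(pM[c] * c2[c] for c in comps)
            sig[:, 0, 3] = sig[:, 3, 0] = sum(kap[c] * pM[c] * c2[c] for c in comps)
            sig[:, 2, 1] = sig[:, 1, 2] = sum(kap[c] * pM[c] * c1[c] for c in comps)
            yy = sum(kap[c] * (c1[c] * c2[c] + u1[c] * u2[c]) for c in comps)
            sig[:, 1, 3] = sig[:, 3, 1] = yy
            mu = np.empty((n, 4))
            mu[:, 0] = mu[:, 2] = 0.0
            mu[:, 0] = x[self._idx("b0_m")] + x[self._idx("bage_m")] * a_c
            mu[:, 2] = mu[:, 0]
            mu[:, 1] = x[self._idx("b0_t")] + x[self._idx("bage_t")] * a_c
            mu[:, 3] = mu[:, 1]
            ydat = np.column_stack([d["m"][:, 0], d["y"][:, 0],
                                    d["m"][:, 1], d["y"][:, 1]])
            val = lk.mvn_m2ll_batched(ydat, mu, sig)
            if val >= lk.REJECT:
                return lk.REJECT
            total += val
            if len(d["solo_y"]):
                sm_c = d["solo_m"] - self.m_center
                sa_c = d["solo_age"] - self.age_center
                cs, us = self._paths(x, sm_c)
                vt = sum(cs[c] ** 2 + us[c] ** 2 for c in comps)
                ctm = sum(pM[c] * cs[c] for c in comps)
                ns = len(sm_c)
                sig2 = np.empty((ns, 2, 2))
                sig2[:, 0, 0] = vM
                sig2[:, 1, 1] = vt
                sig2[:, 0, 1] = sig2[:, 1, 0] = ctm
                mu2 = np.empty((ns, 2))
                mu2[:, 0] = x[self._idx("b0_m")] + x[self._idx("bage_m")] * sa_c
                mu2[:, 1] = x[self._idx("b0_t")] + x[self._idx("bage_t")] * sa_c
                val = lk.mvn_m2ll_batched(
                    np.column_stack([d["solo_m"], d["solo_y"]]), mu2, sig2)
                if val >= lk.REJECT:
                    return lk.REJECT
                total += val
        return total

    def curves(self, x, grid) -> ModeratedVariance:
        m_c = np.asarray(grid) - self.m_center
        common, unique = self._paths(x, m_c)
        zeros = np.zeros_like(m_c)
        comps = _COMP[self.family]
        absA = common["a"] ** 2 + unique["a"] ** 2 + zeros
        dckey = comps[1] if len(comps) == 3 else None
        absDC = ((common[dckey] ** 2 + unique[dckey] ** 2 + zeros)
                 if dckey else zeros)
        absE = common["e"] ** 2 + unique["e"] ** 2 + zeros
        abs_common = sum(common[c] ** 2 for c in comps) + zeros
        abs_unique = sum(unique[c] ** 2 for c in comps) + zeros
        return ModeratedVariance(
            grid=np.asarray(grid), abs_A=absA, abs_DC=absDC, abs_E=absE,
            family="ACE" if self.family == "ACE" else "ADE",
            abs_common=abs_common, abs_unique=abs_unique)


def _run_problem(problem_cls, cohort, spec, sexes, n_restarts, seed, grid):
    fits, curves = {}, {}
    for i, sex in enumerate(sexes):
        if not cohort.frame["zygosity_group"].isin(_SEX_GROUPS[sex]).any():
            continue
        prob = problem_cls(cohort, spec, sex)
        if grid is not None:
            g = np.asarray(grid, dtype=float)
            if g.min() < prob.m_range[0] - 1e-9 or g.max() > prob.m_range[1] + 1e-9:
                raise ValueError("moderator grid extends outside the observed range")
        else:
            g = _default_grid(prob._all_m, spec.grid_points)
        best, agree = lk.multistart_minimize(prob.objective, prob.x0, prob.bounds,
                                             n_restarts=n_restarts,
                                             seed=seed + 31 * i)
        est = {n: float(v) for n, v in zip(prob.param_names, best.x)}
        fr = FitResult(
            estimates=est, minus2ll=float(best.fun),
            n_params=len(prob.param_names), converged=bool(best.success),
            gradient_norm=float(np.abs(best.jac).max()), params=np.asarray(best.x),
            param_names=list(prob.param_names), n_restarts_agreeing=agree,
            _objective=prob.objective, _bounds=prob.bounds)
        fits[sex] = fr
        curves[sex] = prob.curves(best.x, g)
    if not fits:
        raise ValueError("no same-sex data for any requested sex")
    return fits, curves


def fit_full_bivariate_moderation(cohort: Cohort, trait: str, moderator: str,
                                  family: str = "ADE", sexes=("M", "F"),
                                  moderated_paths=("a_common", "d_common", "e_common",
                                                   "a_unique", "d_unique", "e_unique"),
                                  grid=None, grid_points: int = 15,
                                  n_restarts: int = 2, seed: int = 0) -> ModerationFit:
    """Fit the full bivariate moderation model (trait jointly with moderator)."""
    spec = ModerationSpec(trait=trait, moderator=moderator, family=family,
                          moderated_paths=tuple(moderated_paths),
                          grid=grid, grid_points=grid_points)
    fits, curves = _run_problem(_FullBivariateProblem, cohort, spec, sexes,
                                n_restarts, seed, grid)
    return ModerationFit(kind="full_bivariate", spec=spec, fits=fits, curves=curves)


def fit_extended_univariate_moderation(cohort: Cohort, trait: str, moderator: str,
                                       family: str = "ADE", sexes=("M", "F"),
                                       moderated_paths=("a_unique", "d_unique",
                                                        "e_unique"),
                                       grid=None, grid_points: int = 15,
                                       n_restarts: int = 2,
                                       seed: int = 0) -> ModerationFit:
    """Fit the extended univariate moderation model.

    Trait paths are moderated by the twin's own moderator; both twins'
    moderator values enter the means model as main effects.
    """
    spec = ModerationSpec(trait=trait, moderator=moderator, family=family,
                          moderated_paths=tuple(moderated_paths),
                          grid=grid, grid_points=grid_points)
    fits, curves = _run_problem(_ExtendedUnivariateProblem, cohort, spec, sexes,
                                n_restarts, seed, grid)
    return ModerationFit(kind="extended_univariate", spec=spec, fits=fits,
                         curves=curves)


def moderation_test_sequence(cohort: Cohort, trait: str, moderator: str,
                             family: str = "ADE", sexes=("M", "F"),
                             alpha: float = 0.05, n_restarts: int = 1,
                             seed: int = 0) -> dict:
    """LRT ladder deciding which moderation model a trait-moderator pair needs.

    Within the full bivariate structure, per sex: (i) no moderation vs
    moderation of the trait-unique paths; (ii) unique-path moderation vs
    additionally moderating the common (covariance) paths.  The full
    bivariate model is recommended when (ii) is significant for either
    sex, the extended univariate model otherwise.
    """
    from scipy.stats import chi2

    comps = _COMP[family]
    unique = tuple(f"{c}_unique" for c in comps)
    both = unique + tuple(f"{c}_common" for c in comps)
    report = {"per_sex": {}, "alpha": alpha}
    any_cov = False
    any_unique = False
    for sex in sexes:
        if not cohort.frame["zygosity_group"].isin(_SEX_GROUPS[sex]).any():
            continue
        res = {}
        m0 = fit_full_bivariate_moderation(cohort, trait, moderator, family,
                                           sexes=(sex,), moderated_paths=(),
                                           n_restarts=n_restarts, seed=seed)
        m1 = fit_full_bivariate_moderation(cohort, trait, moderator, family,
                                           sexes=(sex,), moderated_paths=unique,
                                           n_restarts=n_restarts, seed=seed)
        m2 = fit_full_bivariate_moderation(cohort, trait, moderator, family,
                                           sexes=(sex,), moderated_paths=both,
                                           n_restarts=n_restarts, seed=seed)
        d1 = max(0.0, m0.minus2ll - m1.minus2ll)
        df1 = m1.n_params - m0.n_params
        p1 = float(chi2.sf(d1, df1))
        d2 = max(0.0, m1.minus2ll - m2.minus2ll)
        df2 = m2.n_params - m1.n_params
        p2 = float(chi2.sf(d2, df2))
        res["unique_moderation"] = {"delta_chi2": d1, "delta_df": df1, "p": p1,
                                    "significant": p1 < alpha}
        res["covariance_moderation"] = {"delta_chi2": d2, "delta_df": df2, "p": p2,
                                        "significant": p2 < alpha}
        any_cov |= p2 < alpha
        any_unique |= p1 < alpha
        report["per_sex"][sex] = res
    report["recommendation"] = ("full_bivariate" if any_cov
                                else "extended_univariate")
    report["any_unique_moderation"] = any_unique
    report["any_covariance_moderation"] = any_cov
    return report
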