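"""Correlated-factor bivariate twin models.

Two traits X and Y are each decomposed into A/D-or-C/E components with
per-trait paths, and like components are allowed to correlate across
traits (r_A, r_D or r_C, r_E).  The cross-twin cross-trait covariance
carries the usual kinship scaling (additive 1 or 1/2, dominance 1 or 1/4,
common environment fully shared).  Quantitative sex limitation is handled
by fitting same-sex male and female groups separately — they share no
parameters, so the joint fit factorizes exactly.

Headline derived quantities:

* broad-sense genetic correlation
  r_H = (a_X a_Y r_A + d_X d_Y r_D) / sqrt((a_X²+d_X²)(a_Y²+d_Y²)) —
  preferred over separate r_A/r_D when A and D are individually unstable;
* implied phenotypic correlation r_P and its decomposition into genetic,
  common-environment and unique-environment source contributions; the
  genetic share of r_P is the bivariate heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Cohort
from . import likelihood as lk
from .likelihood import FitResult

_SEX_GROUPS = {"M": ("MZM", "DZM"), "F": ("MZF", "DZF")}
_KAPPA = {"MZ": (1.0, 1.0), "DZ": (0.5, 0.25)}

#: bound on the unconstrained correlation scale; tanh(8) ≈ 0.9999997
_Z_BOUND = 8.0


@dataclass
class BivariateEstimates:
    """Per-sex estimates from a correlated-factor bivariate fit."""

    traits: tuple
    family: str
    per_sex: dict                      # sex -> dict of named estimates
    fits: dict                         # sex -> FitResult

    @property
    def minus2ll(self) -> float:
        return float(sum(f.minus2ll for f in self.fits.values()))

    @property
    def n_params(self) -> int:
        return int(sum(f.n_params for f in self.fits.values()))

    @property
    def aic(self) -> float:
        return self.minus2ll + 2 * self.n_params


class _BivariateProblem:
    """Single-sex correlated-factor model over MZ and DZ same-sex pairs."""

    def __init__(self, cohort: Cohort, traits, family: str, sex: str,
                 age_degrees=None, mean_free_by_zygosity=()):
        if family not in ("ADE", "ACE", "AE"):
            raise ValueError(f"unsupported bivariate family {family!r}")
        self.traits = tuple(traits)
        self.family = family
        self.sex = sex
        self.degrees = {t: 1 for t in self.traits}
        if age_degrees:
            self.degrees.update(age_degrees)
        self.free_means = tuple(mean_free_by_zygosity)
        frame = cohort.frame
        self.data = {}
        ages_all, count = 0.0, 0
        for zyg, g in zip(("MZ", "DZ"), _SEX_GROUPS[sex]):
            mask = (frame["zygosity_group"] == g).to_numpy()
            if not mask.any():
                continue
            sub = frame.loc[mask]
            cols = [self.traits[0] + "_1", self.traits[1] + "_1",
                    self.traits[0] + "_2", self.traits[1] + "_2"]
            y = sub[cols].to_numpy(dtype=float).copy()
            p1 = sub["present1"].to_numpy(dtype=bool)
            p2 = sub["present2"].to_numpy(dtype=bool)
            y[~p1, :2] = np.nan
            y[~p2, 2:] = np.nan
            keep = ~np.isnan(y).all(axis=1)
            self.data[zyg] = (y[keep], sub["age"].to_numpy(dtype=float)[keep])
        if not self.data:
            raise ValueError(f"no same-sex pairs for sex {sex!r}")
        center = float(np.mean(np.concatenate([a for _, a in self.data.values()])))
        self.data = {z: (y, a - center) for z, (y, a) in self.data.items()}
        self.age_center = center
        self._layout()
        self._starts()

    def _layout(self):
        names, bounds = [], []
        for t in self.traits:
            if t in self.free_means:
                for z in self.data:
                    names.append(f"b0_{t}_{z}")
                    bounds.append((None, None))
            else:
                names.append(f"b0_{t}")
                bounds.append((None, None))
            names += [f"bage{k}_{t}" for k in range(1, self.degrees[t] + 1)]
            bounds += [(None, None)] * self.degrees[t]
            names.append(f"logV_{t}")
            bounds.append((-46.0, 46.0))
            names.append(f"h_{t}")
            bounds.append((0.0, 1.0))
            if self.family in ("ADE", "ACE"):
                names.append(("g_" if self.family == "ADE" else "u_") + t)
                bounds.append((0.0, 1.0))
        comps = {"ADE": ("A", "D", "E"), "ACE": ("A", "C", "E"),
                 "AE": ("A", "E")}[self.family]
        for c in comps:
            names.append(f"z_r{c}")
            bounds.append((-_Z_BOUND, _Z_BOUND))
        self.param_names, self.bounds = names, bounds

    def _idx(self, n):
        return self.param_names.index(n)

    def _starts(self):
        x0 = np.zeros(len(self.param_names))
        iccs = {}
        for j, t in enumerate(self.traits):
            ys, ages = [], []
            for z, (y, a) in self.data.items():
                for col in (j, j + 2):
                    ok = ~np.isnan(y[:, col])
                    ys.append(y[ok, col])
                    ages.append(a[ok])
            yv, av = np.concatenate(ys), np.concatenate(ages)
            deg = self.degrees[t]
            X = np.column_stack([np.ones_like(av)] + [av ** k for k in range(1, deg + 1)])
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            if t in self.free_means:
                for z in self.data:
                    x0[self._idx(f"b0_{t}_{z}")] = beta[0]
            else:
                x0[self._idx(f"b0_{t}")] = beta[0]
            for k in range(1, deg + 1):
                x0[self._idx(f"bage{k}_{t}")] = beta[k]
            x0[self._idx(f"logV_{t}")] = np.log(max(np.var(yv - X @ beta), 1e-12))
            for z, (y, a) in self.data.items():
                both = ~np.isnan(y[:, [j, j + 2]]).any(axis=1)
                if both.sum() > 3:
                    iccs[(t, z)] = float(np.corrcoef(y[both, j], y[both, j + 2])[0, 1])
            rmz = iccs.get((t, "MZ"), 0.4)
            rdz = iccs.get((t, "DZ"), 0.2)
            if self.family == "ACE":
                a2 = np.clip(2 * (rmz - rdz), 0.02, 0.9)
                c2 = np.clip(2 * rdz - rmz, 0.0, 0.9 - a2)
                x0[self._idx(f"h_{t}")] = a2
                x0[self._idx(f"u_{t}")] = np.clip(c2 / max(1e-6, 1 - a2), 0.05, 0.9)
            elif self.family == "ADE":
                a2 = np.clip(4 * rdz - rmz, 0.0, 0.9)
                d2 = np.clip(2 * rmz - 4 * rdz, 0.0, 0.9 - a2)
                x0[self._idx(f"h_{t}")] = np.clip(a2 + d2, 0.05, 0.9)
                x0[self._idx(f"g_{t}")] = np.clip(a2 / max(a2 + d2, 1e-6), 0.05, 0.95)
            else:
                x0[self._idx(f"h_{t}")] = np.clip(rmz, 0.05, 0.9)
        # start component correlations at the scaled phenotypic correlation
        rps = []
        for z, (y, a) in self.data.items():
            ok = ~np.isnan(y[:, 0]) & ~np.isnan(y[:, 1])
            if ok.sum() > 3:
                rps.append(np.corrcoef(y[ok, 0], y[ok, 1])[0, 1])
        rp = float(np.mean(rps)) if rps else 0.0
        for n in self.param_names:
            if n.startswith("z_r"):
                x0[self._idx(n)] = np.arctanh(np.clip(rp, -0.9, 0.9))
        self.x0 = x0

    # -- structure ----------------------------------------------------------
    def _paths(self, x):
        """Per-trait path dict: {trait: (a, d_or_c, e)}."""
        out = {}
        for t in self.traits:
            V = float(np.exp(x[self._idx(f"logV_{t}")]))
            h = x[self._idx(f"h_{t}")]
            if self.family == "ADE":
                g = x[self._idx(f"g_{t}")]
                a2, dc2 = h * g * V, h * (1 - g) * V
            elif self.family == "ACE":
                u = x[self._idx(f"u_{t}")]
                a2, dc2 = h * V, (1 - h) * u * V
            else:
                a2, dc2 = h * V, 0.0
            e2 = V - a2 - dc2
            out[t] = (np.sqrt(a2), np.sqrt(dc2), np.sqrt(max(e2, 1e-300)))
        return out

    def _rs(self, x):
        comps = {"ADE": ("A", "D", "E"), "ACE": ("A", "C", "E"),
                 "AE": ("A", "E")}[self.family]
        return {c: float(np.tanh(x[self._idx(f"z_r{c}")])) for c in comps}

    def _sigma(self, x, zyg):
        tX, tY = self.traits
        (aX, dX, eX), (aY, dY, eY) = self._paths(x)[tX], self._paths(x)[tY]
        rs = self._rs(x)
        rA = rs["A"]
        rDC = rs.get("D", rs.get("C", 0.0))
        rE = rs["E"]
        kA, kD = _KAPPA[zyg]
        if self.family == "ACE":
            kDC_within, kDC_cross = 1.0, 1.0
        else:
            kDC_within, kDC_cross = 1.0, kD
        vX = aX ** 2 + dX ** 2 + eX ** 2
        vY = aY ** 2 + dY ** 2 + eY ** 2
        cw = aX * aY * rA + dX * dY * rDC + eX * eY * rE        # within person
        ciX = kA * aX ** 2 + (1.0 if self.family == "ACE" else kD) * dX ** 2
        ciY = kA * aY ** 2 + (1.0 if self.family == "ACE" else kD) * dY ** 2
        cc = kA * aX * aY * rA + kDC_cross * dX * dY * rDC       # cross twin cross trait
        # order (X1, Y1, X2, Y2)
        return np.array([
            [vX, cw, ciX, cc],
            [cw, vY, cc, ciY],
            [ciX, cc, vX, cw],
            [cc, ciY, cw, vY],
        ])

    def _mu(self, x, zyg, ages):
        cols = []
        for t in self.traits:
            key = f"b0_{t}_{zyg}" if t in self.free_means else f"b0_{t}"
            m = np.full(len(ages), x[self._idx(key)])
            for k in range(1, self.degrees[t] + 1):
                m = m + x[self._idx(f"bage{k}_{t}")] * ages ** k
            cols.append(m)
        return np.column_stack(cols + cols)

    def objective(self, x) -> float:
        total = 0.0
        for zyg, (y, a) in self.data.items():
            val = lk.mvn_m2ll_pattern(y, self._mu(x, zyg, a), self._sigma(x, zyg))
            if val >= lk.REJECT:
                return lk.REJECT
            total += val
        return total

    # -- reporting ----------------------------------------------------------
    def estimates(self, x) -> dict:
        tX, tY = self.traits
        paths = self._paths(x)
        (aX, dX, eX), (aY, dY, eY) = paths[tX], paths[tY]
        rs = self._rs(x)
        rA = rs["A"]
        rDC = rs.get("D", rs.get("C", 0.0))
        rE = rs["E"]
        est = {}
        for t, (a, d, e) in paths.items():
            V = a * a + d * d + e * e
            est[f"V_{t}"] = float(V)
            est[f"a2_{t}"] = float(a * a / V)
            key = "c2" if self.family == "ACE" else "d2"
            est[f"{key}_{t}"] = float(d * d / V)
            est[f"e2_{t}"] = float(e * e / V)
            est[f"H_{t}"] = float((a * a + (d * d if self.family == "ADE" else 0.0)) / V)
        est["r_A"] = rA
        if self.family == "ADE":
            est["r_D"] = rDC
        elif self.family == "ACE":
            est["r_C"] = rDC
        est["r_E"] = rE
        gX, gY = aX * aX + (dX * dX if self.family == "ADE" else 0.0), \
                 aY * aY + (dY * dY if self.family == "ADE" else 0.0)
        gcov = aX * aY * rA + (dX * dY * rDC if self.family == "ADE" else 0.0)
        est["r_H"] = float(gcov / np.sqrt(gX * gY)) if gX > 0 and gY > 0 else np.nan
        ccov = dX * dY * rDC if self.family == "ACE" else 0.0
        ecov = eX * eY * rE
        total_cov = gcov + ccov + ecov
        vX = aX ** 2 + dX ** 2 + eX ** 2
        vY = aY ** 2 + dY ** 2 + eY ** 2
        r_P = total_cov / np.sqrt(vX * vY)
        est["r_P"] = float(r_P)
        if abs(r_P) < 1e-6:
            est["share_genetic"] = est["share_common_env"] = est["share_unique_env"] = np.nan
            est["shares_defined"] = False
        else:
            est["share_genetic"] = float(gcov / total_cov)
            est["share_common_env"] = float(ccov / total_cov)
            est["share_unique_env"] = float(ecov / total_cov)
            est["shares_defined"] = True
        est["boundary_correlations"] = [
            n for n in ("r_A", "r_D", "r_C", "r_E")
            if n in est and abs(est[n]) > 0.999]
        est["age_center"] = self.age_center
        return est


def fit_bivariate(cohort: Cohort, traits, family: str = "ADE",
                  sexlim: str = "quantitative", age_degrees=None,
                  mean_free_by_zygosity=(), sexes=("M", "F"),
                  n_restarts: int = 2, seed: int = 0) -> BivariateEstimates:
    """Fit the correlated-factor bivariate model on same-sex pairs.

    Quantitative sex limitation: every parameter is sex-specific, so male
    and female groups are fitted separately (an exact factorization of the
    joint likelihood).  ``mean_free_by_zygosity`` lists traits whose
    intercepts stay free across MZ/DZ (used for education, where equating
    means across zygosity degrades fit).
    """
    if sexlim != "quantitative":
        raise ValueError("bivariate models support quantitative sex limitation only")
    per_sex, fits = {}, {}
    for i, sex in enumerate(sexes):
        groups = _SEX_GROUPS[sex]
        if not cohort.frame["zygosity_group"].isin(groups).any():
            continue
        prob = _BivariateProblem(cohort, traits, family, sex,
                                 age_degrees, mean_free_by_zygosity)
        best, agree = lk.multistart_minimize(
            prob.objective, prob.x0, prob.bounds,
            n_restarts=n_restarts, seed=seed + 17 * i)
        fr = FitResult(
            estimates=prob.estimates(best.x), minus2ll=float(best.fun),
            n_params=len(prob.param_names), converged=bool(best.success),
            gradient_norm=float(np.abs(best.jac).max()), params=np.asarray(best.x),
            param_names=list(prob.param_names), n_restarts_agreeing=agree,
            _objective=prob.objective, _bounds=prob.bounds,
            _estimator=prob.estimates)
        per_sex[sex] = fr.estimates
        fits[sex] = fr
    if not fits:
        raise ValueError("no same-sex pairs available for any requested sex")
    return BivariateEstimates(traits=tuple(traits), family=family,
                              per_sex=per_sex, fits=fits)


def decompose_rp(est: BivariateEstimates) -> dict:
    """Source decomposition of the implied phenotypic correlation, per sex.

    r_P = Σ_source √(share_X) √(share_Y) r_source; each source contribution
    divided by r_P is its share (genetic combines A and D — the bivariate
    heritability).  Shares are undefined when |r_P| is numerically zero.
    """
    out = {}
    for sex, e in est.per_sex.items():
        out[sex] = {
            "r_P": e["r_P"],
            "defined": bool(e["shares_defined"]),
            "genetic": e["share_genetic"],
            "common_env": e["share_common_env"],
            "unique_env": e["share_unique_env"],
        }
    return out


def compare_bivariate_families(cohort: Cohort, traits, families=("ADE", "ACE", "AE"),
                               age_degrees=None, mean_free_by_zygosity=(),
                               sexes=("M", "F"), n_restarts: int = 2,
                               seed: int = 0) -> dict:
    """AIC ranking of bivariate families against the saturated baseline.

    Fits each structured family plus the constrained saturated model on the
    same same-sex data and reports AIC, the LRT against the saturated
    model, and whether every structured family rejects against it.
    """
    from scipy.stats import chi2
    from .saturated import fit_saturated

    sub = cohort.subset_groups([g for s in sexes for g in _SEX_GROUPS[s]])
    sat = fit_saturated(sub, traits, adjust_age=age_degrees, pooled=False,
                        n_restarts=1, seed=seed)
    sat_m2, sat_k = sat.minus2ll, sat.n_params
    report = {"saturated": {"minus2LL": sat_m2, "n_params": sat_k,
                            "AIC": sat_m2 + 2 * sat_k}, "models": {}}
    for fam in families:
        est = fit_bivariate(cohort, traits, family=fam, age_degrees=age_degrees,
                            mean_free_by_zygosity=mean_free_by_zygosity,
                            sexes=sexes, n_restarts=n_restarts, seed=seed)
        dchi = max(0.0, est.minus2ll - sat_m2)
        ddf = sat_k - est.n_params
        p = float(chi2.sf(dchi, ddf)) if ddf > 0 else np.nan
        report["models"][fam] = {
            "minus2LL": est.minus2ll, "n_params": est.n_params, "AIC": est.aic,
            "lrt_vs_saturated": {"delta_chi2": dchi, "delta_df": ddf, "p": p},
            "estimates": est.per_sex,
        }
    ranked = sorted(report["models"], key=lambda f: report["models"][f]["AIC"])
    report["aic_ranking"] = ranked
    report["best_by_aic"] = ranked[0]
    report["all_reject_vs_saturated"] = all(
        report["models"][f]["lrt_vs_saturated"]["p"] < 0.05 for f in families)
    return report
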