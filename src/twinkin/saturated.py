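"""Constrained saturated models: descriptive twin correlations by FIML.

For each zygosity group an unstructured multivariate normal is fitted to
the stacked co-twin phenotype vectors, with means, variances and
within-individual cross-trait correlations equated across twin order
(twin order is arbitrary in same-sex pairs).  Age is regressed out of the
means inside the model — linear or quadratic per trait — so that twin
correlations are not inflated by co-twins sharing an age.  The fit yields,
per group, the three descriptive correlation families of the twin design:

* phenotypic (within-individual, cross-trait),
* intraclass (same trait across co-twins),
* cross-twin cross-trait (trait X in twin 1 with trait Y in twin 2,
  equated across direction).

Pooled MZ / DZ / total rows are re-fitted with the groups merged rather
than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import Cohort, GROUP_SEXES, ZYGOSITY_GROUPS
from . import likelihood as lk
from .likelihood import FitResult


@dataclass
class CorrelationTable:
    """Per-group descriptive correlations with fit bookkeeping."""

    traits: list
    rows: pd.DataFrame                 # one row per group/pooled label
    fits: dict = field(default_factory=dict)   # label -> FitResult

    @property
    def minus2ll(self) -> float:
        return float(sum(f.minus2ll for f in self.fits.values()))

    @property
    def n_params(self) -> int:
        return int(sum(f.n_params for f in self.fits.values()))

    def row(self, label: str) -> pd.Series:
        return self.rows.set_index("group").loc[label]

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.4f")


class _SaturatedGroupProblem:
    """One group's unstructured 2T-variate normal with order-equating."""

    def __init__(self, y, ages, traits, degrees, equate_positions: bool):
        self.y = y                     # (n, 2T): twin1 traits then twin2 traits
        self.age_c = ages - ages.mean()
        self.traits = traits
        self.T = len(traits)
        self.degrees = degrees
        self.eq = equate_positions
        self._layout()
        self._starts()

    def _layout(self):
        names, bounds = [], []
        positions = (1,) if self.eq else (1, 2)
        for pos in positions:
            tag = "" if self.eq else f"_p{pos}"
            for t in self.traits:
                names += [f"b0_{t}{tag}"]
                bounds += [(None, None)]
                names += [f"bage{k}_{t}{tag}" for k in range(1, self.degrees[t] + 1)]
                bounds += [(None, None)] * self.degrees[t]
                names += [f"logV_{t}{tag}"]
                bounds += [(-46.0, 46.0)]
        for tx, ty in combinations(self.traits, 2):
            names.append(f"rp_{tx}_{ty}")          # within-individual (phenotypic)
            bounds.append((-0.999, 0.999))
        for t in self.traits:
            names.append(f"ricc_{t}")              # intraclass
            bounds.append((-0.999, 0.999))
        for tx, ty in combinations(self.traits, 2):
            names.append(f"rctct_{tx}_{ty}")       # cross-twin cross-trait
            bounds.append((-0.999, 0.999))
        self.param_names, self.bounds = names, bounds

    def _idx(self, n):
        return self.param_names.index(n)

    def _starts(self):
        x0 = np.zeros(len(self.param_names))
        T = self.T
        for j, t in enumerate(self.traits):
            cols = [j, j + T]
            vals = self.y[:, cols]
            ok = ~np.isnan(vals)
            pooled = vals[ok]
            ages = np.concatenate([self.age_c[ok[:, 0]], self.age_c[ok[:, 1]]])
            deg = self.degrees[t]
            X = np.column_stack([np.ones_like(ages)] +
                                [ages ** k for k in range(1, deg + 1)])
            beta, *_ = np.linalg.lstsq(X, pooled, rcond=None)
            rv = max(float(np.var(pooled - X @ beta)), 1e-12)
            positions = (1,) if self.eq else (1, 2)
            for pos in positions:
                tag = "" if self.eq else f"_p{pos}"
                x0[self._idx(f"b0_{t}{tag}")] = beta[0]
                for k in range(1, deg + 1):
                    x0[self._idx(f"bage{k}_{t}{tag}")] = beta[k]
                x0[self._idx(f"logV_{t}{tag}")] = np.log(rv)
            both = ok.all(axis=1)
            if both.sum() > 3:
                x0[self._idx(f"ricc_{t}")] = np.clip(
                    np.corrcoef(vals[both, 0], vals[both, 1])[0, 1], -0.9, 0.9)
        for tx, ty in combinations(self.traits, 2):
            jx, jy = self.traits.index(tx), self.traits.index(ty)
            a = np.concatenate([self.y[:, jx], self.y[:, jx + T]])
            b = np.concatenate([self.y[:, jy], self.y[:, jy + T]])
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() > 3:
                x0[self._idx(f"rp_{tx}_{ty}")] = np.clip(
                    np.corrcoef(a[ok], b[ok])[0, 1], -0.9, 0.9)
            c1 = ~np.isnan(self.y[:, jx]) & ~np.isnan(self.y[:, jy + T])
            if c1.sum() > 3:
                x0[self._idx(f"rctct_{tx}_{ty}")] = np.clip(
                    np.corrcoef(self.y[c1, jx], self.y[c1, jy + T])[0, 1], -0.9, 0.9)
        self.x0 = x0

    def _sigma(self, x):
        T = self.T
        sd = np.empty(2 * T)
        for pos in (1, 2):
            tag = "" if self.eq else f"_p{pos}"
            for j, t in enumerate(self.traits):
                sd[j + (pos - 1) * T] = np.exp(0.5 * x[self._idx(f"logV_{t}{tag}")])
        R = np.eye(2 * T)
        for tx, ty in combinations(self.traits, 2):
            jx, jy = self.traits.index(tx), self.traits.index(ty)
            rp = x[self._idx(f"rp_{tx}_{ty}")]
            R[jx, jy] = R[jy, jx] = rp
            R[jx + T, jy + T] = R[jy + T, jx + T] = rp
            rc = x[self._idx(f"rctct_{tx}_{ty}")]
            R[jx, jy + T] = R[jy + T, jx] = rc
            R[jy, jx + T] = R[jx + T, jy] = rc
        for j, t in enumerate(self.traits):
            ric = x[self._idx(f"ricc_{t}")]
            R[j, j + T] = R[j + T, j] = ric
        return R * np.outer(sd, sd)

    def _mu(self, x):
        T = self.T
        mu = np.empty((len(self.y), 2 * T))
        for pos in (1, 2):
            tag = "" if self.eq else f"_p{pos}"
            for j, t in enumerate(self.traits):
                m = np.full(len(self.y), x[self._idx(f"b0_{t}{tag}")])
                for k in range(1, self.degrees[t] + 1):
                    m = m + x[self._idx(f"bage{k}_{t}{tag}")] * self.age_c ** k
                mu[:, j + (pos - 1) * T] = m
        return mu

    def objective(self, x) -> float:
        return lk.mvn_m2ll_pattern(self.y, self._mu(x), self._sigma(x))


def _group_arrays(cohort: Cohort, traits, groups):
    """Stacked (n, 2T) arrays for a set of zygosity groups, OS male-first."""
    frame = cohort.frame
    mask = frame["zygosity_group"].isin(groups).to_numpy()
    sub = frame.loc[mask]
    cols1 = [t + "_1" for t in traits]
    cols2 = [t + "_2" for t in traits]
    y = np.column_stack([sub[cols1].to_numpy(dtype=float),
                         sub[cols2].to_numpy(dtype=float)])
    p1 = sub["present1"].to_numpy(dtype=bool)
    p2 = sub["present2"].to_numpy(dtype=bool)
    T = len(traits)
    y[~p1, :T] = np.nan
    y[~p2, T:] = np.nan
    keep = ~np.isnan(y).all(axis=1)
    return y[keep], sub["age"].to_numpy(dtype=float)[keep]


_POOLED = {"MZ": ("MZM", "MZF"), "DZ": ("DZM", "DZF", "DZOS"),
           "Total": ZYGOSITY_GROUPS}


def fit_saturated(cohort: Cohort, traits, adjust_age=None,
                  pooled: bool = True, ci: bool = False,
                  n_restarts: int = 1, seed: int = 0) -> CorrelationTable:
    """Constrained saturated fit per zygosity group (and pooled rows).

    ``adjust_age`` maps trait name to polynomial degree of the age effect
    on means (default 1).  Groups with fewer than two complete pairs are
    reported as unavailable.  With ``ci=True``, 95% profile-likelihood
    intervals are attached for every correlation (slower).
    """
    traits = list(traits)
    degrees = {t: 1 for t in traits}
    if adjust_age:
        degrees.update(adjust_age)
    labels = [g for g in ZYGOSITY_GROUPS
              if (cohort.frame["zygosity_group"] == g).any()]
    jobs = {g: (g,) for g in labels}
    if pooled:
        for lab, gs in _POOLED.items():
            if sum(g in labels for g in gs) > 1:
                jobs[lab] = gs
    rows, fits = [], {}
    for label, groups in jobs.items():
        y, ages = _group_arrays(cohort, traits, groups)
        complete = (~np.isnan(y[:, :len(traits)]).all(axis=1)
                    & ~np.isnan(y[:, len(traits):]).all(axis=1)).sum()
        if complete < 2:
            rows.append({"group": label, "available": False})
            continue
        equate = label != "DZOS"
        prob = _SaturatedGroupProblem(y, ages, traits, degrees, equate)
        best, agree = lk.multistart_minimize(prob.objective, prob.x0, prob.bounds,
                                             n_restarts=n_restarts, seed=seed)
        fr = FitResult(
            estimates={n: float(v) for n, v in zip(prob.param_names, best.x)},
            minus2ll=float(best.fun), n_params=len(prob.param_names),
            converged=bool(best.success), gradient_norm=float(np.abs(best.jac).max()),
            params=np.asarray(best.x), param_names=list(prob.param_names),
            n_restarts_agreeing=agree, _objective=prob.objective,
            _bounds=prob.bounds)
        fits[label] = fr
        row = {"group": label, "available": True, "n_pairs": int(len(y)),
               "minus2LL": fr.minus2ll, "n_params": fr.n_params}
        for t in traits:
            row[f"icc_{t}"] = fr.estimates[f"ricc_{t}"]
        for tx, ty in combinations(traits, 2):
            row[f"r_pheno_{tx}_{ty}"] = fr.estimates[f"rp_{tx}_{ty}"]
            row[f"r_ctct_{tx}_{ty}"] = fr.estimates[f"rctct_{tx}_{ty}"]
        if ci:
            for pname in prob.param_names:
                if pname.startswith(("ricc_", "rp_", "rctct_")):
                    lo, hi = lk.profile_ci(prob.objective, fr.params, fr.minus2ll,
                                           prob.param_names.index(pname),
                                           prob.bounds)
                    fr.ci[pname] = (lo, hi)
                    row[f"ci_{pname}"] = f"({lo:.3f}, {hi:.3f})"
        rows.append(row)
    return CorrelationTable(traits=traits, rows=pd.DataFrame(rows), fits=fits)


# ---------------------------------------------------------------------------
# assumption checks


class _TraitGroupMoments:
    """Single-trait saturated problem over several groups with optional
    equating of means/variances across twin order and across zygosity."""

    def __init__(self, cohort, trait, equate_order, equate_zygosity):
        self.trait = trait
        self.eq_o = equate_order
        self.eq_z = equate_zygosity
        self.data = {}
        frame = cohort.frame
        ages_all = frame["age"].to_numpy(dtype=float)
        center = float(ages_all.mean())
        for g in ZYGOSITY_GROUPS:
            mask = (frame["zygosity_group"] == g).to_numpy()
            if not mask.any():
                continue
            sub = frame.loc[mask]
            y = sub[[trait + "_1", trait + "_2"]].to_numpy(dtype=float).copy()
            y[~sub["present1"].to_numpy(dtype=bool), 0] = np.nan
            y[~sub["present2"].to_numpy(dtype=bool), 1] = np.nan
            keep = ~np.isnan(y).all(axis=1)
            if keep.sum() > 1:
                self.data[g] = (y[keep], sub["age"].to_numpy(dtype=float)[keep] - center)
        self._layout()
        self._starts()

    def _slots(self):
        """(group, position) -> moment-parameter tag under current equating."""
        slots = {}
        for g in self.data:
            for pos in (1, 2):
                sex = GROUP_SEXES[g][pos - 1]
                if self.eq_z:
                    tag = f"sex{sex}"
                elif self.eq_o and g != "DZOS":
                    tag = g
                else:
                    tag = f"{g}_p{pos}"
                slots[(g, pos)] = tag
        return slots

    def _layout(self):
        self.slots = self._slots()
        names, bounds = [], []
        for tag in dict.fromkeys(self.slots.values()):
            names += [f"b0_{tag}", f"bage_{tag}", f"logV_{tag}"]
            bounds += [(None, None), (None, None), (-46.0, 46.0)]
        for g in self.data:
            names.append(f"r_{g}")
            bounds.append((-0.999, 0.999))
        self.param_names, self.bounds = names, bounds

    def _idx(self, n):
        return self.param_names.index(n)

    def _starts(self):
        x0 = np.zeros(len(self.param_names))
        for tag in dict.fromkeys(self.slots.values()):
            ys, ages = [], []
            for (g, pos), t in self.slots.items():
                if t != tag:
                    continue
                y, a = self.data[g]
                ok = ~np.isnan(y[:, pos - 1])
                ys.append(y[ok, pos - 1])
                ages.append(a[ok])
            yv, av = np.concatenate(ys), np.concatenate(ages)
            X = np.column_stack([np.ones_like(av), av])
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            x0[self._idx(f"b0_{tag}")] = beta[0]
            x0[self._idx(f"bage_{tag}")] = beta[1]
            x0[self._idx(f"logV_{tag}")] = np.log(max(np.var(yv - X @ beta), 1e-12))
        for g, (y, a) in self.data.items():
            both = ~np.isnan(y).any(axis=1)
            if both.sum() > 3:
                x0[self._idx(f"r_{g}")] = np.clip(
                    np.corrcoef(y[both, 0], y[both, 1])[0, 1], -0.9, 0.9)
        self.x0 = x0

    def objective(self, x) -> float:
        total = 0.0
        for g, (y, a) in self.data.items():
            mus, sds = [], []
            for pos in (1, 2):
                tag = self.slots[(g, pos)]
                mus.append(x[self._idx(f"b0_{tag}")] + x[self._idx(f"bage_{tag}")] * a)
                sds.append(np.exp(0.5 * x[self._idx(f"logV_{tag}")]))
            r = x[self._idx(f"r_{g}")]
            sigma = np.array([[sds[0] ** 2, r * sds[0] * sds[1]],
                              [r * sds[0] * sds[1], sds[1] ** 2]])
            total += lk.mvn_m2ll_pattern(y, np.column_stack(mus), sigma)
        return total

    def fit(self, seed=0):
        best, _ = lk.multistart_minimize(self.objective, self.x0, self.bounds,
                                         n_restarts=1, seed=seed)
        return float(best.fun), len(self.param_names)


def equal_order_zygosity_check(cohort: Cohort, traits, alpha: float = 0.05,
                               seed: int = 0) -> dict:
    """LRT-based check of the twin-design moment assumptions per trait.

    Compares (i) means/variances free per twin position vs equated across
    twin order, and (ii) order-equated vs additionally equated across
    zygosity groups (within sex).  Traits whose test p-value falls below
    ``alpha`` are flagged.  With a single zygosity group the zygosity
    comparison is skipped.
    """
    from scipy.stats import chi2

    report = {}
    for t in traits:
        free = _TraitGroupMoments(cohort, t, equate_order=False, equate_zygosity=False)
        if len(free.data) == 0:
            report[t] = {"available": False}
            continue
        m2_free, k_free = free.fit(seed)
        eq_o = _TraitGroupMoments(cohort, t, equate_order=True, equate_zygosity=False)
        m2_o, k_o = eq_o.fit(seed)
        d1, df1 = max(0.0, m2_o - m2_free), k_free - k_o
        p_order = float(chi2.sf(d1, df1)) if df1 > 0 else 1.0
        entry = {"available": True,
                 "order": {"delta_chi2": d1, "delta_df": df1, "p": p_order,
                           "violated": p_order < alpha}}
        if len(free.data) > 1:
            eq_z = _TraitGroupMoments(cohort, t, equate_order=True, equate_zygosity=True)
            m2_z, k_z = eq_z.fit(seed)
            d2, df2 = max(0.0, m2_z - m2_o), k_o - k_z
            p_z = float(chi2.sf(d2, df2)) if df2 > 0 else 1.0
            entry["zygosity"] = {"delta_chi2": d2, "delta_df": df2, "p": p_z,
                                 "violated": p_z < alpha}
        else:
            entry["zygosity"] = {"skipped": "single zygosity group"}
        report[t] = entry
    return report
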