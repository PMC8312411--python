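"""Twin-cohort containers and CSV I/O.

The canonical in-memory layout is *wide*: one row per twin pair with
``_1``/``_2`` column suffixes for the two twins.  Zygosity is coded in five
groups — MZM, MZF (monozygotic male/female), DZM, DZF (dizygotic same-sex)
and DZOS (dizygotic opposite-sex).  Within opposite-sex pairs twin 1 is
always the male; readers reorder so the non-symmetric opposite-sex expected
covariance has a fixed orientation.  Singleton respondents (one twin of a
pair missing) are retained because they still inform means, variances and
within-individual covariances under full-information maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZYGOSITY_GROUPS = ("MZM", "MZF", "DZM", "DZF", "DZOS")
SAME_SEX_GROUPS = ("MZM", "MZF", "DZM", "DZF")
#: sex of (twin1, twin2) implied by each zygosity group
GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "DZOS": ("M", "F"),
}

_BASE_COLUMNS = ("pair_id", "zygosity_group", "sex1", "sex2", "age", "present1", "present2")


@dataclass
class TwinPairRecord:
    """One twin pair (or singleton).

    ``phenotypes`` maps a trait name to a ``(twin1, twin2)`` value pair;
    missing values are ``nan``.  Co-twins share a single age.
    """

    pair_id: str
    zygosity_group: str
    sex: tuple[str, str]
    age: float
    phenotypes: dict[str, tuple[float, float]] = field(default_factory=dict)
    present: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        if self.zygosity_group not in ZYGOSITY_GROUPS:
            raise ValueError(f"unknown zygosity group {self.zygosity_group!r}")
        expected = GROUP_SEXES[self.zygosity_group]
        if tuple(self.sex) != expected:
            raise ValueError(
                f"sexes {self.sex} inconsistent with zygosity group "
                f"{self.zygosity_group} (expected {expected})"
            )
        if not any(self.present):
            raise ValueError("a pair must have at least one present twin")


class Cohort:
    """A collection of twin pairs with named phenotypes.

    Thin wrapper around a wide-format :class:`pandas.DataFrame`; the frame
    is the working representation for all likelihood code.
    """

    def __init__(self, frame: pd.DataFrame, phenotype_names: list[str]):
        missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort frame lacks columns {missing}")
        if frame["pair_id"].duplicated().any():
            raise ValueError("pair_ids must be unique")
        for p in phenotype_names:
            for suf in ("_1", "_2"):
                if p + suf not in frame.columns:
                    raise ValueError(f"phenotype column {p + suf} missing")
        self.frame = frame.reset_index(drop=True)
        self.phenotype_names = list(phenotype_names)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.phenotype_names != other.phenotype_names:
            return False
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            x, y = a[c].to_numpy(), b[c].to_numpy()
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                x = np.asarray(x, dtype=float)
                y = np.asarray(y, dtype=float)
                if not np.allclose(x, y, equal_nan=True, rtol=0, atol=1e-12):
                    return False
            elif not (x == y).all():
                return False
        return True

    @property
    def n_individuals(self) -> int:
        return int(self.frame["present1"].sum() + self.frame["present2"].sum())

    def records(self) -> list[TwinPairRecord]:
        out = []
        for _, row in self.frame.iterrows():
            out.append(
                TwinPairRecord(
                    pair_id=str(row["pair_id"]),
                    zygosity_group=row["zygosity_group"],
                    sex=(row["sex1"], row["sex2"]),
                    age=float(row["age"]),
                    phenotypes={
                        p: (float(row[p + "_1"]), float(row[p + "_2"]))
                        for p in self.phenotype_names
                    },
                    present=(bool(row["present1"]), bool(row["present2"])),
                )
            )
        return out

    @classmethod
    def from_records(cls, records: list[TwinPairRecord], phenotype_names=None) -> "Cohort":
        if phenotype_names is None:
            phenotype_names = sorted({p for r in records for p in r.phenotypes})
        rows = []
        for r in records:
            row = {
                "pair_id": r.pair_id,
                "zygosity_group": r.zygosity_group,
                "sex1": r.sex[0],
                "sex2": r.sex[1],
                "age": r.age,
                "present1": r.present[0],
                "present2": r.present[1],
            }
            for p in phenotype_names:
                v1, v2 = r.phenotypes.get(p, (np.nan, np.nan))
                row[p + "_1"], row[p + "_2"] = v1, v2
            rows.append(row)
        cols = list(_BASE_COLUMNS) + [p + s for p in phenotype_names for s in ("_1", "_2")]
        frame = pd.DataFrame(rows, columns=cols)
        return cls(frame, list(phenotype_names))

    def subset_groups(self, groups) -> "Cohort":
        keep = self.frame["zygosity_group"].isin(list(groups))
        return Cohort(self.frame.loc[keep].reset_index(drop=True), self.phenotype_names)

    def group_counts(self) -> pd.DataFrame:
        """Individuals and complete pairs per zygosity group (descriptives layout)."""
        rows = []
        for g in ZYGOSITY_GROUPS:
            sub = self.frame[self.frame["zygosity_group"] == g]
            n_ind = int(sub["present1"].sum() + sub["present2"].sum())
            n_complete = int((sub["present1"] & sub["present2"]).sum())
            rows.append({"zygosity_group": g, "n_individuals": n_ind,
                         "n_complete_pairs": n_complete,
                         "n_singletons": len(sub) - n_complete})
        return pd.DataFrame(rows)


def _finalize_pair_row(row: dict, phenotype_names) -> dict | None:
    """Validate zygosity/sex coding of a raw wide row; reorder DZOS male-first.

    Returns the cleaned row, or None if the zygosity code is unknown
    (rejected with a warning).  Inconsistent sex/zygosity coding is a hard
    error.
    """
    g = row["zygosity_group"]
    if g not in ZYGOSITY_GROUPS:
        logger.warning("rejecting pair %s: unknown zygosity code %r", row["pair_id"], g)
        return None
    s1, s2 = row["sex1"], row["sex2"]
    # a missing co-twin inherits the sex its group implies
    exp1, exp2 = GROUP_SEXES[g]
    if s1 is None:
        s1 = exp1 if g != "DZOS" else ("M" if s2 == "F" else "F")
    if s2 is None:
        s2 = exp2 if g != "DZOS" else ("M" if s1 == "F" else "F")
    if g == "DZOS":
        if {s1, s2} != {"M", "F"}:
            raise ValueError(f"pair {row['pair_id']}: DZOS pair with sexes ({s1},{s2})")
        if s1 == "F":  # canonical orientation: twin 1 is the male
            row = dict(row)
            row["sex1"], row["sex2"] = "M", "F"
            row["present1"], row["present2"] = row["present2"], row["present1"]
            for p in phenotype_names:
                row[p + "_1"], row[p + "_2"] = row[p + "_2"], row[p + "_1"]
            return row
    else:
        if (s1, s2) != GROUP_SEXES[g]:
            raise ValueError(
                f"pair {row['pair_id']}: sexes ({s1},{s2}) inconsistent with {g}"
            )
    row = dict(row)
    row["sex1"], row["sex2"] = s1, s2
    return row


def read_cohort(path, schema: dict | None = None, format: str = "auto") -> Cohort:
    """Read a twin cohort from CSV.

    Accepts the canonical wide layout (one row per pair; columns
    ``pair_id, zygosity_group, sex1, sex2, age, <pheno>_1, <pheno>_2`` and
    optional ``present1/present2``) or a long layout (one row per twin;
    columns ``pair_id, zygosity_group, sex, age`` plus phenotype columns),
    which is converted to wide.  ``schema`` optionally renames columns
    (``{"csv column": "canonical name"}``).  Empty cells are missing values.
    """
    raw = pd.read_csv(path, dtype={"pair_id": str})
    if schema:
        raw = raw.rename(columns=schema)
    if format == "auto":
        format = "wide" if "sex1" in raw.columns else "long"
    if format == "long":
        raw = _long_to_wide(raw)
    pheno = sorted(
        {c[:-2] for c in raw.columns if c.endswith("_1") and c[:-2] + "_2" in raw.columns
         and c not in ("present_1",)}
    )
    if "present1" not in raw.columns:
        raw["present1"] = ~raw[[p + "_1" for p in pheno]].isna().all(axis=1) if pheno else True
    if "present2" not in raw.columns:
        raw["present2"] = ~raw[[p + "_2" for p in pheno]].isna().all(axis=1) if pheno else True
    rows = []
    for _, r in raw.iterrows():
        d = r.to_dict()
        d["sex1"] = None if pd.isna(d.get("sex1")) else d.get("sex1")
        d["sex2"] = None if pd.isna(d.get("sex2")) else d.get("sex2")
        cleaned = _finalize_pair_row(d, pheno)
        if cleaned is not None:
            rows.append(cleaned)
    cols = list(_BASE_COLUMNS) + [p + s for p in pheno for s in ("_1", "_2")]
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan
    frame = frame[cols]
    frame["present1"] = frame["present1"].astype(bool)
    frame["present2"] = frame["present2"].astype(bool)
    frame["age"] = frame["age"].astype(float)
    for p in pheno:
        frame[p + "_1"] = frame[p + "_1"].astype(float)
        frame[p + "_2"] = frame[p + "_2"].astype(float)
    return Cohort(frame, pheno)


def _long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    value_cols = [c for c in long.columns
                  if c not in ("pair_id", "zygosity_group", "sex", "age", "twin")]
    rows = {}
    for _, r in long.iterrows():
        pid = r["pair_id"]
        entry = rows.setdefault(pid, {
            "pair_id": pid, "zygosity_group": r["zygosity_group"], "age": r["age"],
            "sex1": None, "sex2": None, "present1": False, "present2": False,
        })
        slot = 1 if entry["sex1"] is None and not entry["present1"] else 2
        # explicit twin index wins over arrival order
        if "twin" in long.columns and not pd.isna(r.get("twin")):
            slot = int(r["twin"])
        entry[f"sex{slot}"] = r["sex"]
        entry[f"present{slot}"] = True
        for c in value_cols:
            entry[f"{c}_{slot}"] = r[c]
    wide = pd.DataFrame(list(rows.values()))
    for c in value_cols:
        for s in ("_1", "_2"):
            if c + s not in wide.columns:
                wide[c + s] = np.nan
    return wide


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical wide CSV; missing numeric cells become empty strings."""
    out = cohort.frame.copy()
    out["present1"] = out["present1"].astype(bool)
    out["present2"] = out["present2"].astype(bool)
    out.to_csv(path, index=False, na_rep="")


def validate_summary(cohort: Cohort) -> str:
    """Human-readable group-count table (descriptives layout)."""
    counts = cohort.group_counts()
    lines = [f"{'group':<6}{'individuals':>13}{'complete pairs':>16}{'singletons':>12}"]
    for _, r in counts.iterrows():
        lines.append(f"{r['zygosity_group']:<6}{r['n_individuals']:>13}"
                     f"{r['n_complete_pairs']:>16}{r['n_singletons']:>12}")
    lines.append(f"total individuals: {cohort.n_individuals}")
    return "\n".join(lines)
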