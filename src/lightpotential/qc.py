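"""Rule-based quality-control flagging.

Field phenotyping data carry instrument faults, user error (leaf
movement) and low signal-to-noise measurements whose derived parameters
fall outside theoretical ranges.  Flags are kept alongside the data —
excluded rows disappear only from the analysis *view*, never from the
stored table.

Rules are declarative: each has a ``rule_id``, the parameter columns it
checks (per phase where applicable) and a closed range.  Thresholds
encode the theoretical ranges of the parameters (e.g. phi2 and qL are
fractions; g_H+ decay rates beyond 500 s⁻¹ are unresolvable within a
300 ms dark interval) and are overridable via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .derive import PHASES

FLAG_COLUMNS = ["leaf_id", "rule_id", "reason", "severity"]


@dataclass(frozen=True)
class QcFlag:
    leaf_id: str
    rule_id: str
    reason: str
    severity: str = "exclude"   # or "warn"


#: rule_id -> (column stem expanded per phase, low, high)
DEFAULT_RANGE_RULES: dict[str, tuple[str, float, float]] = {
    "phi2_range": ("phi2", 0.0, 1.0),
    "ql_range": ("ql", 0.0, 1.0),
    "npqt_range": ("npqt", -0.1, 15.0),
    "ecst_range": ("ecst", 0.0, np.inf),
    "gh_plus_range": ("gh_plus", np.nextafter(0.0, 1.0), 500.0),
    "dirk_r2": ("ecs_r2", 0.5, np.inf),
    "dirk_r2_p700": ("p700_r2", 0.5, np.inf),
    "fluor_inversion": ("__fluor__", np.nan, np.nan),   # fm' > fs, special-cased
}


def flag_device(records: pd.DataFrame, blacklist: list[str]) -> pd.DataFrame:
    """One exclude-flag per record from a blacklisted device."""
    flags = []
    blacklist = set(blacklist or [])
    if blacklist and "device_id" in records:
        for leaf_id, dev in zip(records["leaf_id"], records["device_id"]):
            if dev in blacklist:
                flags.append(QcFlag(str(leaf_id), "device_blacklist",
                                    f"defective device {dev}", "exclude"))
    return _to_frame(flags)


def flag_ranges(records: pd.DataFrame,
                rules: dict[str, tuple[str, float, float]] | None = None) -> pd.DataFrame:
    """Flag records whose derived parameters leave their theoretical ranges.

    ``rules`` overrides/extends the defaults; an unknown column stem in a
    user rule is a configuration error.  A NaN value never triggers a
    range flag by itself (missingness carries its own reason in the
    derive notes), but failed DIRK fits surface through the R² rules
    because failed fits report their (low) R².
    """
    rules = {**DEFAULT_RANGE_RULES, **(rules or {})}
    known_stems = {stem for stem, _, _ in DEFAULT_RANGE_RULES.values()}
    flags: list[QcFlag] = []
    for rule_id, (stem, lo, hi) in rules.items():
        if stem == "__fluor__":
            for phase in PHASES:
                fs_col, fm_col = f"fs_{phase}", f"fm_prime_{phase}"
                if fs_col not in records or fm_col not in records:
                    continue
                bad = records[fm_col] <= records[fs_col]
                for leaf_id in records.loc[bad.fillna(False), "leaf_id"]:
                    flags.append(QcFlag(str(leaf_id), rule_id,
                                        f"fm_prime <= fs in phase {phase}", "exclude"))
            continue
        cols = [f"{stem}_{phase}" for phase in PHASES if f"{stem}_{phase}" in records]
        if not cols:
            if stem in records.columns:
                cols = [stem]
            elif stem not in known_stems:
                raise KeyError(f"rule {rule_id!r} references unknown column {stem!r}")
            else:
                continue
        for col in cols:
            vals = records[col]
            bad = (vals < lo) | (vals > hi)
            for leaf_id, v in zip(records.loc[bad.fillna(False), "leaf_id"],
                                  vals[bad.fillna(False)]):
                flags.append(QcFlag(str(leaf_id), rule_id,
                                    f"{col}={v:.4g} outside [{lo:.4g}, {hi:.4g}]",
                                    "exclude"))
    return _to_frame(flags)


def apply_qc(records: pd.DataFrame, flags: pd.DataFrame,
             mode: str = "exclude") -> pd.DataFrame:
    """Produce the analysis view.

    ``exclude`` drops exclude-flagged rows (the stored table is
    untouched); ``keep`` returns all rows annotated with their flags.
    """
    if mode not in ("exclude", "keep"):
        raise ValueError(f"unknown mode {mode!r}")
    if flags.empty:
        excluded: set[str] = set()
    else:
        excluded = set(flags.loc[flags["severity"] == "exclude", "leaf_id"].astype(str))
    if mode == "exclude":
        out = records[~records["leaf_id"].astype(str).isin(excluded)].copy()
        return out.reset_index(drop=True)
    out = records.copy()
    if flags.empty:
        out["qc_flags"] = ""
    else:
        joined = flags.groupby("leaf_id")["rule_id"].apply(
            lambda s: ";".join(sorted(set(s))))
        out["qc_flags"] = out["leaf_id"].astype(str).map(joined).fillna("")
    return out


def run_qc(records: pd.DataFrame, blacklist: list[str] | None = None,
           rules: dict | None = None) -> pd.DataFrame:
    """Device + range flags combined, de-duplicated (set semantics)."""
    flags = pd.concat(
        [flag_device(records, blacklist or []), flag_ranges(records, rules)],
        ignore_index=True,
    )
    return flags.drop_duplicates().sort_values(FLAG_COLUMNS).reset_index(drop=True)


def _to_frame(flags: list[QcFlag]) -> pd.DataFrame:
    if not flags:
        return pd.DataFrame(columns=FLAG_COLUMNS)
    return pd.DataFrame([vars(f) for f in flags], columns=FLAG_COLUMNS)
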