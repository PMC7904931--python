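"""Statistical comparisons and study report assembly.

Condition means are compared by one-way ANOVA followed by Tukey's HSD
post-test within each lipid system (the two families of interest are each
compound vs. control and each glycoside vs. its aglycone), and by a
two-way ANOVA (compound x lipid system, with interaction) across the full
design.  Significance is encoded on the conventional ladder:
* P<0.05, ** P<0.01, *** P<0.001, **** P<0.0001.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import (
    AGLYCONE_OF,
    Compound,
    LipidSystem,
    write_results_table,
)

__all__ = [
    "SignificanceCode",
    "ComparisonResult",
    "significance_code",
    "one_way_anova_tukey",
    "two_way_anova",
    "build_report",
]

_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


class SignificanceCode(enum.Enum):
    NS = "ns"
    ONE = "*"
    TWO = "**"
    THREE = "***"
    FOUR = "****"


def significance_code(p_value: float) -> SignificanceCode:
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p_value}")
    for threshold, stars in _LADDER:
        if p_value < threshold:
            return SignificanceCode(stars)
    return SignificanceCode.NS


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    p_value: float
    code: SignificanceCode
    mean_diff: float
    family: str = "all-pairs"  # "vs-control" / "vs-aglycone" flagged on top

    def __post_init__(self):
        if significance_code(self.p_value) is not self.code:
            raise ValueError("significance code inconsistent with p-value")


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, list[ComparisonResult]]:
    """Omnibus one-way ANOVA F-test, then all-pairs Tukey HSD.

    Returns (omnibus p, comparisons).  Comparisons against CONTROL and
    against the matching aglycone are flagged via their ``family`` field;
    unbalanced group sizes get the Tukey-Kramer adjustment (the statsmodels
    behaviour).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    labels, data = [], []
    for name, vals in groups.items():
        labels.extend([name] * len(vals))
        data.extend(float(v) for v in vals)
    f_stat, omnibus_p = sps.f_oneway(*[np.asarray(v, float) for v in groups.values()])
    tk = pairwise_tukeyhsd(np.asarray(data), np.asarray(labels), alpha=0.05)
    results = []
    # full-precision p-values live on the attributes (the summary rounds)
    pairs = list(zip(*np.triu_indices(len(tk.groupsunique), k=1)))
    for (i, j), p_adj, mdiff in zip(pairs, tk.pvalues, tk.meandiffs):
        a, b = str(tk.groupsunique[i]), str(tk.groupsunique[j])
        family = "all-pairs"
        pair = {a, b}
        if Compound.CONTROL.name in pair:
            family = "vs-control"
        else:
            for glyc, agly in AGLYCONE_OF.items():
                if pair == {glyc.name, agly.name}:
                    family = "vs-aglycone"
                    break
        p = float(min(max(p_adj, 0.0), 1.0))
        results.append(
            ComparisonResult(
                group_a=a,
                group_b=b,
                p_value=p,
                code=significance_code(p),
                mean_diff=float(mdiff),
                family=family,
            )
        )
    return float(omnibus_p), results


def two_way_anova(data: pd.DataFrame, response: str = "value") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (compound x lipid_system, interaction).

    ``data`` needs columns ``compound``, ``lipid_system`` and the response.
    Returns the type-II ANOVA table with F statistics and p-values.
    """
    for col in ("compound", "lipid_system", response):
        if col not in data.columns:
            raise ValueError(f"data missing column {col!r}")
    counts = data.groupby(["compound", "lipid_system"]).size()
    n_cells = data["compound"].nunique() * data["lipid_system"].nunique()
    if len(counts) < n_cells:
        raise ValueError("empty cells in the compound x lipid_system design")
    model = smf.ols(
        f"{response} ~ C(compound) * C(lipid_system)", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(compound)": "compound",
            "C(lipid_system)": "lipid_system",
            "C(compound):C(lipid_system)": "interaction",
        }
    )
    return table


# ---------------------------------------------------------------------------
# report bundle

def build_report(
    rex_replicates: pd.DataFrame,
    anisotropy_results: Sequence,
    lifetime_rows: pd.DataFrame | None,
    dipole_shifts: Sequence,
    out_dir: str | Path,
    run_info: dict | None = None,
) -> dict[str, Path]:
    """Assemble the final study tables and a run log.

    * ``rex_replicates``: columns lipid_system, compound, replicate, rex
      (per-sample ratios; Tukey codes vs. control are attached per system);
    * ``anisotropy_results``: AnisotropyResult records;
    * ``lifetime_rows``: per-sample mean lifetimes (may be None);
    * ``dipole_shifts``: DipoleShift records.

    Regeneration from identical inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # R_ex table with significance codes vs control
    rex_rows = []
    for system, sub in rex_replicates.groupby("lipid_system", sort=True):
        groups = {
            comp: g["rex"].tolist() for comp, g in sub.groupby("compound", sort=True)
        }
        codes: dict[str, str] = {}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            _, comparisons = one_way_anova_tukey(groups)
            for c in comparisons:
                if c.family == "vs-control":
                    other = (
                        c.group_a if c.group_b == Compound.CONTROL.name else c.group_b
                    )
                    codes[other] = c.code.value  # "ns" included, per the ladder
        for comp, vals in groups.items():
            arr = np.asarray(vals, float)
            rex_rows.append(
                {
                    "lipid_system": system,
                    "compound": comp,
                    "estimate": round(float(arr.mean()), 6),
                    "sd": round(float(arr.std(ddof=1)) if arr.size > 1 else 0.0, 6),
                    "n": int(arr.size),
                    "vs_control": codes.get(comp, ""),
                }
            )
    paths["rex"] = write_results_table(rex_rows, out_dir / "rex.tsv")

    # anisotropy table
    aniso_rows = [
        {
            "lipid_system": r.condition[0],
            "compound": r.condition[1],
            "estimate": round(r.mean_r, 6),
            "sd": round(r.sd_r, 6),
            "n": r.n_samples,
        }
        for r in anisotropy_results
    ]
    paths["anisotropy"] = write_results_table(aniso_rows, out_dir / "anisotropy.tsv")

    # mean lifetime table
    if lifetime_rows is not None and not lifetime_rows.empty:
        lt_rows = []
        for (system, comp), g in lifetime_rows.groupby(
            ["lipid_system", "compound"], sort=True
        ):
            arr = g["mean_tau_ns"].to_numpy(float)
            lt_rows.append(
                {
                    "lipid_system": system,
                    "compound": comp,
                    "estimate": round(float(arr.mean()), 6),
                    "sd": round(float(arr.std(ddof=1)) if arr.size > 1 else 0.0, 6),
                    "n": int(arr.size),
                }
            )
        paths["lifetime"] = write_results_table(lt_rows, out_dir / "lifetime.tsv")

    # dipole shift table
    shift_rows = [
        {
            "lipid_system": s.condition[0],
            "compound": s.condition[1],
            "estimate": round(s.delta_psi_mV, 6),
            "sd": round(s.sd_mV, 6),
            "n": "",
            "delta_rex": round(s.delta_rex, 6),
        }
        for s in dipole_shifts
    ]
    paths["dipole"] = write_results_table(shift_rows, out_dir / "dipole_shifts.tsv")

    # run log with a content hash of the emitted tables
    log = dict(run_info or {})
    digest = hashlib.sha256()
    for key in sorted(paths):
        digest.update(paths[key].read_bytes())
    log["tables_sha256"] = digest.hexdigest()
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    paths["log"] = log_path
    return paths
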