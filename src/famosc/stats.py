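"""Group statistics: the normality-gated dispatch and the report builder.

The dispatch rule used for every two-group contrast: Shapiro-Wilk on each
sample at α = 0.05; when both pass, the parametric path (ANOVA F, with
Tukey-HSD posthoc when a second factor is present), otherwise the two-sided
Mann-Whitney U rank-sum. Distribution shapes (CDFs) are compared with the
two-sample Kolmogorov-Smirnov test and paired designs with the Wilcoxon
signed-rank test. The tests themselves are delegated to scipy/pingouin; the
dispatch logic and reporting are this module's contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .types import ValidationError, _require

SHAPIRO_ALPHA = 0.05
#: Rank tests use exact p-values up to this per-group n (no ties), else the
#: asymptotic normal approximation with continuity correction.
EXACT_N_MAX = 25


@dataclass
class GroupSample:
    """A labelled sample of one metric, optionally keyed for pairing."""

    label: str
    values: np.ndarray
    pairing_keys: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _require(self.values.ndim == 1 and self.values.size >= 1,
                 f"group {self.label!r}: at least one value required")
        if self.pairing_keys is not None:
            _require(len(self.pairing_keys) == self.values.size,
                     f"group {self.label!r}: one pairing key per value")


@dataclass
class ComparisonResult:
    test: str  # {mann-whitney, anova+tukey, ks, wilcoxon}
    statistic: float
    p_value: float
    groups: tuple[str, str]
    n: tuple[int, int]
    normality: tuple[Optional[bool], Optional[bool]] = (None, None)
    effect_direction: str = ""  # label of the group with the larger center
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value),
                 "p-value outside [0, 1]")


def _direction(a: GroupSample, b: GroupSample) -> str:
    da, db = float(np.median(a.values)), float(np.median(b.values))
    if da == db:
        return "none"
    return a.label if da > db else b.label


def compare_groups(a: GroupSample, b: GroupSample,
                   alpha: float = SHAPIRO_ALPHA) -> ComparisonResult:
    """Normality-gated two-group contrast.

    Samples with fewer than 3 values cannot be Shapiro-tested; the rank-sum
    path is forced with a warning. The result records which gate fired.
    """
    small = a.values.size < 3 or b.values.size < 3
    if small:
        warnings.warn("sample(s) too small for the normality gate; forcing "
                      "the rank-sum path", stacklevel=2)
        normality: tuple[Optional[bool], Optional[bool]] = (None, None)
        parametric = False
    else:
        pa = sps.shapiro(a.values).pvalue
        pb = sps.shapiro(b.values).pvalue
        normality = (bool(pa > alpha), bool(pb > alpha))
        parametric = normality[0] and normality[1]
    if parametric:
        stat, p = sps.f_oneway(a.values, b.values)
        if not np.isfinite(p) and stat <= 1e-12:
            stat, p = 0.0, 1.0  # identical groups: F rounds below 0
        test = "anova+tukey"
    else:
        stat, p = _mannwhitney(a.values, b.values)
        test = "mann-whitney"
    return ComparisonResult(test=test, statistic=float(stat),
                            p_value=float(p), groups=(a.label, b.label),
                            n=(a.values.size, b.values.size),
                            normality=normality,
                            effect_direction=_direction(a, b))


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = ("exact" if (max(x.size, y.size) <= EXACT_N_MAX and no_ties)
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ks_compare(a: GroupSample, b: GroupSample) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a − ECDF_b|."""
    res = sps.ks_2samp(a.values, b.values, alternative="two-sided")
    return ComparisonResult(test="ks", statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            groups=(a.label, b.label),
                            n=(a.values.size, b.values.size),
                            effect_direction=_direction(a, b))


def paired_compare(a: GroupSample, b: GroupSample) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank on aligned pairs.

    Pairs are aligned by ``pairing_keys`` when both samples carry them,
    otherwise by position. Zero differences are dropped (documented policy);
    all-zero differences leave the test undefined.
    """
    if a.pairing_keys is not None and b.pairing_keys is not None:
        kb = {k: v for k, v in zip(b.pairing_keys, b.values)}
        missing = [k for k in a.pairing_keys if k not in kb]
        _require(not missing, f"unmatched pairing keys {missing[:5]}")
        x = a.values
        y = np.array([kb[k] for k in a.pairing_keys])
    else:
        _require(a.values.size == b.values.size,
                 "paired samples must have equal length")
        x, y = a.values, b.values
    d = x - y
    if np.all(d == 0):
        raise ValidationError("all paired differences are zero; signed-rank "
                              "test undefined")
    nz = int(np.count_nonzero(d))
    method = "exact" if nz <= EXACT_N_MAX else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return ComparisonResult(test="wilcoxon", statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            groups=(a.label, b.label),
                            n=(x.size, y.size),
                            effect_direction=_direction(a, b),
                            detail={"n_nonzero_diffs": nz})


def vep_amplitude_anova(amplitudes: dict[str, np.ndarray]) -> dict:
    """Two-way ANOVA (group × cycle) with Tukey-HSD posthoc per cycle.

    ``amplitudes`` maps each group label to an animals × cycles array of VEP
    amplitudes. Returns the interaction F/p and, per cycle, the Tukey table
    of pairwise group contrasts.
    """
    import pandas as pd
    import pingouin as pg

    rows = []
    for label, arr in amplitudes.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        for animal in range(arr.shape[0]):
            for cyc in range(arr.shape[1]):
                rows.append({"group": label, "cycle": cyc + 1,
                             "amplitude": arr[animal, cyc]})
    df = pd.DataFrame(rows)
    aov = pg.anova(data=df, dv="amplitude", between=["group", "cycle"],
                   detailed=True)
    punc = "p_unc" if "p_unc" in aov.columns else "p-unc"
    inter = aov[aov["Source"] == "group * cycle"]
    posthoc: dict[int, list[dict]] = {}
    for cyc, sub in df.groupby("cycle"):
        tuk = pg.pairwise_tukey(data=sub, dv="amplitude", between="group")
        pcol = "p_tukey" if "p_tukey" in tuk.columns else "p-tukey"
        posthoc[int(cyc)] = [
            {"A": r["A"], "B": r["B"], "p_tukey": float(r[pcol])}
            for _, r in tuk.iterrows()]
    return {"test": "anova+tukey",
            "interaction_F": float(inter["F"].iloc[0]),
            "interaction_p": float(inter[punc].iloc[0]),
            "tukey_by_cycle": posthoc}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(
            obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def build_report(metrics: dict, comparisons: list[ComparisonResult],
                 qc: dict | None = None) -> dict:
    """Machine-readable report of every metric and contrast.

    Deterministic: keys sorted, comparisons listed in input order with their
    dispatch decision, n per group and direction; byte-identical JSON for
    identical inputs (``report_json``).
    """
    comp_rows = []
    for c in comparisons:
        comp_rows.append({
            "test": c.test, "groups": list(c.groups), "n": list(c.n),
            "statistic": c.statistic, "p_value": c.p_value,
            "normality": list(c.normality),
            "effect_direction": c.effect_direction,
            "detail": _jsonable(c.detail)})
    report = {"metrics": _jsonable(metrics), "comparisons": comp_rows}
    if qc is not None:
        report["qc"] = _jsonable(qc)
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True, allow_nan=False,
                      default=str)


def report_text(report: dict) -> str:
    """Human-readable table of the report's comparisons and metrics."""
    lines = ["== metrics =="]
    for k, v in sorted(report.get("metrics", {}).items()):
        lines.append(f"{k}: {v}")
    lines.append("== comparisons ==")
    for c in report.get("comparisons", []):
        lines.append(
            f"{c['groups'][0]} vs {c['groups'][1]}: {c['test']} "
            f"stat={c['statistic']:.4g} p={c['p_value']:.3g} "
            f"n={tuple(c['n'])} direction={c['effect_direction']}")
    if "qc" in report:
        lines.append("== qc ==")
        lines.append(json.dumps(report["qc"], sort_keys=True))
    return "\n".join(lines) + "\n"
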