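"""Germline-DMR classification and preimplantation methylation dynamics.

Regions are classified from gamete methylomes alone (oocyte/sperm-specific,
both, or neither), tracked across developmental stages, scored for
post-fertilization protection (blastocyst retention relative to the
methylated gamete), and screened for transient maternal DMRs: an
allele-specific difference present at blastocyst that is resolved -- both
alleles methylated -- in the post-implantation epiblast.  Group comparisons
(ZFP57-bound vs unbound at a stage) use the Mann-Whitney rank-sum test, exact
for small samples and normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

__all__ = [
    "STAGES",
    "MethMatrix",
    "MethConfig",
    "ProtectionResult",
    "classify_gdmr",
    "protection_score",
    "group_compare",
    "sperm_class_check",
    "ranksum_exact",
]

STAGES = (
    "oocyte", "sperm", "zygote", "two_cell", "four_cell", "eight_cell",
    "morula", "ICM", "TE_lineage", "epiblast", "ExE",
)


@dataclass(frozen=True)
class MethConfig:
    """Thresholds for gDMR classes and transient-DMR calling."""

    hi: float = 0.75           # methylated-gamete threshold
    lo: float = 0.25           # unmethylated-gamete threshold
    allele_delta: float = 0.30  # maternal-paternal difference defining a DMR
    blastocyst_stage: str = "ICM"
    epiblast_stage: str = "epiblast"
    min_gamete: float = 0.05   # retention undefined below this gamete level

    def __post_init__(self):
        if not (0 <= self.lo < self.hi <= 1):
            raise ValueError("need 0 <= lo < hi <= 1")


class MethMatrix:
    """Region x stage methylation fractions with optional allele layers.

    Backed by a DataFrame indexed by region_id with one column per stage,
    optional ``<stage>.mat`` / ``<stage>.pat`` allele columns, and a boolean
    ``bound`` column (ZFP57-bound in ES cells).  Values outside [0,1] are
    rejected; NaN means missing.
    """

    def __init__(self, df: pd.DataFrame, stages: Sequence[str] = STAGES):
        self.stages = tuple(stages)
        self.df = df
        for col in df.columns:
            base = col.split(".")[0]
            if base in self.stages:
                v = df[col].to_numpy(dtype=float)
                if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                    raise ValueError(f"column {col} outside [0,1]")

    @property
    def region_ids(self) -> List[str]:
        return list(self.df.index)

    @property
    def has_alleles(self) -> bool:
        return any(c.endswith(".mat") for c in self.df.columns)

    def value(self, region: str, stage: str, allele: Optional[str] = None) -> float:
        col = stage if allele is None else f"{stage}.{allele}"
        return float(self.df.loc[region, col])

    def bound(self, region: str) -> bool:
        return bool(self.df.loc[region, "bound"])

    @classmethod
    def read_tsv(cls, path, stages: Sequence[str] = STAGES) -> "MethMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(df, stages)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="region_id")


def classify_gdmr(oocyte_m: float, sperm_m: float, hi: float = 0.75, lo: float = 0.25) -> str:
    """Gamete-only germline-DMR class: OOCYTE / SPERM / BOTH / NONE."""
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    if oocyte_m is None or sperm_m is None or np.isnan(oocyte_m) or np.isnan(sperm_m):
        return "NONE"
    if oocyte_m >= hi and sperm_m >= hi:
        return "BOTH"
    if oocyte_m >= hi and sperm_m <= lo:
        return "OOCYTE"
    if sperm_m >= hi and oocyte_m <= lo:
        return "SPERM"
    return "NONE"


@dataclass
class ProtectionResult:
    region_id: str
    gdmr_class: str
    blastocyst_retention: float  # NaN when undefined
    transient_dmr: bool
    resolved_in_epiblast: bool
    bound: bool = False


def protection_score(
    matrix: MethMatrix, region: str, cfg: MethConfig = MethConfig()
) -> ProtectionResult:
    """Retention of gamete methylation at blastocyst plus transient-DMR status.

    Retention = blastocyst methylation / methylated-gamete methylation (mean
    of both gametes for the BOTH class).  A transient DMR requires allele
    layers: maternal - paternal >= delta at blastocyst, and resolution means
    that difference has dropped below delta in the epiblast with the epiblast
    total >= hi.
    """
    oo = matrix.value(region, "oocyte")
    sp = matrix.value(region, "sperm")
    cls = classify_gdmr(oo, sp, cfg.hi, cfg.lo)
    blast = matrix.value(region, cfg.blastocyst_stage)

    if cls == "OOCYTE":
        gamete = oo
    elif cls == "SPERM":
        gamete = sp
    elif cls == "BOTH":
        gamete = (oo + sp) / 2.0
    else:
        gamete = max(oo, sp)
    retention = blast / gamete if gamete >= cfg.min_gamete else float("nan")

    transient = resolved = False
    if matrix.has_alleles:
        dm = matrix.value(region, cfg.blastocyst_stage, "mat") - matrix.value(
            region, cfg.blastocyst_stage, "pat"
        )
        dmr_at_blast = bool(dm >= cfg.allele_delta)
        if dmr_at_blast:
            de = matrix.value(region, cfg.epiblast_stage, "mat") - matrix.value(
                region, cfg.epiblast_stage, "pat"
            )
            epi_total = matrix.value(region, cfg.epiblast_stage)
            resolved = bool(abs(de) < cfg.allele_delta and epi_total >= cfg.hi)
        # a transient DMR is one that forms post-fertilization and then
        # resolves; a persistent allele difference (an imprint) is not transient
        transient = dmr_at_blast and resolved
    bound = bool(matrix.df.loc[region].get("bound", False))
    return ProtectionResult(region, cls, retention, transient, resolved, bound)


# -- rank-sum machinery ----------------------------------------------------


def ranksum_exact(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney test via the permutation distribution.

    Handles ties through midranks: a dynamic program over doubled midranks
    enumerates the distribution of the group-A rank sum across all
    C(n_a+n_b, n_a) assignments, which is the exact permutation null.
    Returns (U statistic for group A, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r2 = np.round(ranks * 2).astype(np.int64)  # doubled midranks are integers
    w_obs = int(r2[:na].sum())

    # dp[k] = dict sum -> count of ways to pick k items with that doubled-rank sum
    total = int(r2.sum())
    counts = np.zeros((na + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:
        for k in range(na, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[na]
    n_total = dist.sum()  # = C(na+nb, na)
    mean_w = (na * (na + nb + 1))  # doubled scale: na*(N+1)/2 *2
    dev = abs(w_obs - mean_w)
    sums = np.arange(total + 1)
    p = float(dist[np.abs(sums - mean_w) >= dev - 1e-9].sum() / n_total)
    u = r2[:na].sum() / 2.0 - na * (na + 1) / 2.0
    return float(u), min(p, 1.0)


def group_compare(
    matrix: MethMatrix,
    stage: str,
    cfg: MethConfig = MethConfig(),
    exact_max_n: int = 12,
    values_a: Optional[Sequence[float]] = None,
    values_b: Optional[Sequence[float]] = None,
) -> Dict[str, float]:
    """Bound-vs-unbound rank-sum comparison of methylation at one stage.

    Explicit ``values_a``/``values_b`` override the matrix grouping (used for
    arbitrary group comparisons).  Exact permutation p for groups of up to
    *exact_max_n* each; tie-corrected normal approximation above.
    """
    if values_a is None or values_b is None:
        vals = matrix.df[stage].to_numpy(dtype=float)
        bound = matrix.df["bound"].to_numpy(dtype=bool)
        values_a = vals[bound]
        values_b = vals[~bound]
    a = np.asarray([v for v in values_a if not np.isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not np.isnan(v)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 non-missing values per group")
    if max(len(a), len(b)) <= exact_max_n:
        u, p = ranksum_exact(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return {
        "U": u,
        "p_value": p,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": len(a),
        "n_b": len(b),
        "method": method,
    }


def sperm_class_check(results: Sequence[ProtectionResult]) -> pd.DataFrame:
    """Median blastocyst retention per gDMR class x bound status."""
    rows = []
    classes = sorted({r.gdmr_class for r in results})
    for cls in classes:
        for bound in (True, False):
            sub = [
                r.blastocyst_retention
                for r in results
                if r.gdmr_class == cls and r.bound == bound and not np.isnan(r.blastocyst_retention)
            ]
            if sub:
                rows.append(
                    {
                        "gdmr_class": cls,
                        "bound": bound,
                        "n": len(sub),
                        "median_retention": float(np.median(sub)),
                    }
                )
    return pd.DataFrame(rows)


def protection_to_dataframe(results: Sequence[ProtectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "gdmr_class": [r.gdmr_class for r in results],
            "blastocyst_retention": [r.blastocyst_retention for r in results],
            "transient_dmr": [r.transient_dmr for r in results],
            "resolved_in_epiblast": [r.resolved_in_epiblast for r in results],
            "bound": [r.bound for r in results],
        }
    )
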