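"""Case-control replication analysis under a dominant carrier model.

Per variant, genotype tallies are collapsed to carrier (>= 1 alternate
allele) vs. non-carrier counts, a 2x2 test is chosen by the classical
expected-count rule — Fisher's exact test when any expected cell is below
5, otherwise Pearson's chi-square without continuity correction — and the
odds ratio is reported with a Woolf (log-scale normal) 95% confidence
interval:

    OR = ad / bc,   CI = exp( ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) )

Rows where only one genotype class was observed, or where a 2x2 margin is
zero, are flagged ``not_available`` instead of aborting the batch. Rows
with a zero *cell* keep their test p-value but report no OR/CI (the Woolf
estimator is undefined there). Per-variant denominators are taken as given
— genotyping missingness makes them differ across variants — and are never
renormalized to the cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GenotypeCounts",
    "AssociationResult",
    "collapse_carriers",
    "select_test",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "odds_ratio_woolf",
    "carrier_case_fraction",
    "associate_all",
    "read_replication_table",
    "write_association_table",
]

Z_95 = 1.96  #: normal quantile used for the 95% Woolf interval

#: test selection / availability labels
TESTS = ("chi_square", "fisher", "not_available")


@dataclass(frozen=True)
class GenotypeCounts:
    """Carrier-collapsed 2x2 table.

    Layout (rows = carrier status, columns = group)::

        a = case_carriers      c = control_carriers
        b = case_noncarriers   d = control_noncarriers
    """

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int
    genotype_labels: str = ""

    def __post_init__(self) -> None:
        for name in ("case_carriers", "case_noncarriers", "control_carriers",
                     "control_noncarriers"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def abcd(self) -> tuple[int, int, int, int]:
        return (self.case_carriers, self.case_noncarriers,
                self.control_carriers, self.control_noncarriers)

    @property
    def table(self) -> np.ndarray:
        a, b, c, d = self.abcd
        return np.array([[a, b], [c, d]])

    @property
    def total(self) -> int:
        return sum(self.abcd)


@dataclass(frozen=True)
class AssociationResult:
    """One replication-table row: counts, test choice, p, OR and 95% CI.

    ``p_value`` / ``odds_ratio`` / CI bounds are NaN where not estimable;
    ``reason`` carries a short machine-readable explanation.
    """

    variant: str
    counts: GenotypeCounts
    test_used: str
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    significant: bool
    gene: str = ""
    rs_id: str = ""
    reason: str = ""


GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


def collapse_carriers(
    case_tally: Mapping[str, int],
    control_tally: Mapping[str, int],
    genotype_labels: str = "",
) -> GenotypeCounts:
    """Collapse per-genotype tallies to the dominant-model 2x2 table.

    Carriers = het + hom_alt; non-carriers = hom_ref; ``missing`` entries
    are excluded from both margins.
    """
    def carriers(t: Mapping[str, int]) -> int:
        return int(t.get("het", 0)) + int(t.get("hom_alt", 0))

    return GenotypeCounts(
        case_carriers=carriers(case_tally),
        case_noncarriers=int(case_tally.get("hom_ref", 0)),
        control_carriers=carriers(control_tally),
        control_noncarriers=int(control_tally.get("hom_ref", 0)),
        genotype_labels=genotype_labels,
    )


def n_genotype_classes(case_tally: Mapping[str, int],
                       control_tally: Mapping[str, int]) -> int:
    """Number of distinct genotype classes observed across both groups."""
    return sum(
        1 for g in GENOTYPE_CLASSES
        if case_tally.get(g, 0) + control_tally.get(g, 0) > 0
    )


def select_test(c: GenotypeCounts, expected_threshold: float = 5.0) -> str:
    """Expected-count rule: ``fisher`` if any expected cell under the null of
    independence is below ``expected_threshold``, else ``chi_square``;
    ``not_available`` when a 2x2 margin is zero."""
    a, b, cc, d = c.abcd
    n = a + b + cc + d
    margins = (a + b, cc + d, a + cc, b + d)
    if n == 0 or any(m == 0 for m in margins):
        return "not_available"
    r1, r2, c1, c2 = margins
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    return "fisher" if expected_min < expected_threshold else "chi_square"


def chi_square_2x2(c: GenotypeCounts) -> float:
    """Pearson chi-square p-value (1 df, no continuity correction)."""
    if select_test(c) == "not_available":
        return float("nan")
    stat = stats.chi2_contingency(c.table, correction=False).statistic
    return float(stats.chi2.sf(stat, 1))


def fisher_exact_2x2(c: GenotypeCounts, alternative: str = "two-sided") -> float:
    """Fisher exact p-value. Two-sided (default): the summed probability,
    under the hypergeometric null with fixed margins, of all tables no more
    probable than the observed one; ``greater`` tests for carrier excess in
    cases. Degenerate tables (zero margin) return 1."""
    a, b, cc, d = c.abcd
    if a + b + cc + d == 0:
        return 1.0
    return float(stats.fisher_exact(c.table, alternative=alternative)[1])


def odds_ratio_woolf(
    c: GenotypeCounts, z: float = Z_95
) -> tuple[float, float, float]:
    """Sample odds ratio with Woolf (log-normal) confidence interval.

    Returns ``(nan, nan, nan)`` when any cell is zero: the Woolf standard
    error ``sqrt(1/a + 1/b + 1/c + 1/d)`` is undefined there.
    """
    a, b, cc, d = c.abcd
    if min(a, b, cc, d) == 0:
        return (float("nan"),) * 3
    or_ = (a * d) / (b * cc)
    se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    return (or_, or_ * math.exp(-z * se), or_ * math.exp(z * se))


def carrier_case_fraction(c: GenotypeCounts) -> tuple[float, float]:
    """Percent of carriers who are cases, and percent of non-carriers who
    are cases (the "X% vs. Y%" presentation of a dominant-model signal)."""
    a, b, cc, d = c.abcd
    carrier_total = a + cc
    noncarrier_total = b + d
    pct_carrier = 100.0 * a / carrier_total if carrier_total else float("nan")
    pct_noncarrier = 100.0 * b / noncarrier_total if noncarrier_total else float("nan")
    return pct_carrier, pct_noncarrier


# ---------------------------------------------------------------------------
# Batch analysis
# ---------------------------------------------------------------------------

_REPL_REQUIRED = {"variant", "group", "genotype", "count"}


def read_replication_table(path: str | Path) -> pd.DataFrame:
    """Read a long-form replication tally TSV with columns
    ``variant  group  genotype  count`` (optional ``gene``, ``rs_id``).
    ``group`` is ``case``/``control``; ``genotype`` one of hom_ref/het/
    hom_alt/missing."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant": str})
    missing = _REPL_REQUIRED - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: replication table missing columns "
                              f"{sorted(missing)}")
    bad_groups = set(df["group"]) - {"case", "control"}
    if bad_groups:
        raise ValidationError(f"{path}: unknown group labels {sorted(bad_groups)}")
    return df


def associate_variant(
    variant: str,
    case_tally: Mapping[str, int],
    control_tally: Mapping[str, int],
    alpha: float = 0.05,
    z: float = Z_95,
    expected_threshold: float = 5.0,
    gene: str = "",
    rs_id: str = "",
    genotype_labels: str = "",
) -> AssociationResult:
    """Run the full per-variant analysis: collapse, test selection, p-value,
    OR and CI. Degenerate rows degrade to ``not_available``."""
    counts = collapse_carriers(case_tally, control_tally, genotype_labels)
    nan = float("nan")
    if n_genotype_classes(case_tally, control_tally) <= 1:
        return AssociationResult(variant, counts, "not_available", nan, nan,
                                 nan, nan, False, gene, rs_id,
                                 reason="single_genotype_class")
    test = select_test(counts, expected_threshold)
    if test == "not_available":
        return AssociationResult(variant, counts, test, nan, nan, nan, nan,
                                 False, gene, rs_id, reason="zero_margin")
    p = chi_square_2x2(counts) if test == "chi_square" else fisher_exact_2x2(counts)
    or_, lo, hi = odds_ratio_woolf(counts, z)
    reason = "zero_cell_no_or" if math.isnan(or_) else ""
    return AssociationResult(variant, counts, test, p, or_, lo, hi,
                             significant=bool(p < alpha), gene=gene,
                             rs_id=rs_id, reason=reason)


def associate_all(
    table: pd.DataFrame,
    alpha: float = 0.05,
    z: float = Z_95,
    expected_threshold: float = 5.0,
) -> list[AssociationResult]:
    """Analyze every variant in a long-form tally table (see
    :func:`read_replication_table`); one result per variant, input order.
    Row-level failures are reported as ``not_available`` results, never
    raised."""
    results: list[AssociationResult] = []
    if table.empty:
        return results
    for variant, sub in table.groupby("variant", sort=False):
        tallies: dict[str, dict[str, int]] = {"case": {}, "control": {}}
        for _, row in sub.iterrows():
            g = str(row["genotype"])
            tallies[str(row["group"])][g] = (
                tallies[str(row["group"])].get(g, 0) + int(row["count"]))
        gene = str(sub["gene"].iloc[0]) if "gene" in sub.columns else ""
        rs_id = str(sub["rs_id"].iloc[0]) if "rs_id" in sub.columns else ""
        results.append(associate_variant(
            str(variant), tallies["case"], tallies["control"], alpha=alpha,
            z=z, expected_threshold=expected_threshold, gene=gene, rs_id=rs_id))
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabulate results, adding supplementary Bonferroni / BH-FDR columns.

    The ``significant`` flag stays the uncorrected per-variant one (the
    replication design tested pre-selected variants at alpha = 0.05 without
    multiplicity correction); the corrected columns are provided for
    transparency only.
    """
    rows = []
    for r in results:
        pct_carrier, pct_noncarrier = carrier_case_fraction(r.counts)
        a, b, c, d = r.counts.abcd
        rows.append({
            "variant": r.variant, "gene": r.gene, "rs_id": r.rs_id,
            "case_carriers": a, "case_noncarriers": b,
            "control_carriers": c, "control_noncarriers": d,
            "pct_cases_among_carriers": pct_carrier,
            "pct_cases_among_noncarriers": pct_noncarrier,
            "test_used": r.test_used, "p_value": r.p_value,
            "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "significant": r.significant,
            "reason": r.reason,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    defined = df["p_value"].notna()
    m = int(defined.sum())
    df["p_bonferroni"] = np.nan
    df["q_fdr_bh"] = np.nan
    if m:
        pvals = df.loc[defined, "p_value"].to_numpy()
        df.loc[defined, "p_bonferroni"] = np.minimum(pvals * m, 1.0)
        df.loc[defined, "q_fdr_bh"] = stats.false_discovery_control(pvals, method="bh")
    return df


def write_association_table(results: Sequence[AssociationResult],
                            path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
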