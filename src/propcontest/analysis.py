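"""End-to-end overbidding analysis of a contest cohort.

:class:`ContestAnalysis` is the model object: it wraps a long-format
cohort table (participant x period bids with condition labels and
demographic controls) together with a contest specification, and
``fit()`` produces a :class:`ContestAnalysisResults` bundle holding

* per-condition overbidding-rate summaries over period-level condition
  means (the rate table) and raw expenditure summaries (the
  expenditure table);
* one-sample t tests of expenditures against the equilibrium bid;
* a one-way ANOVA of overbidding rates at the period level (three
  groups of one rate per period) with Bonferroni-adjusted pairwise t
  tests, and a one-way ANOVA of expenditures at the observation level;
* a Levene homogeneity gate that, when violated at ``alpha``, adds the
  nonparametric branch (Kruskal-Wallis plus pairwise Mann-Whitney);
* at-equilibrium and above-equilibrium bid proportions with pairwise
  Fisher exact tests;
* Silverman-bandwidth kernel densities of bids per condition;
* the random-effects panel regression of individual overbidding
  (bid - e*) on condition dummies and demographic controls, with
  standard errors clustered by participant.

The unit-of-analysis choices mirror the experimental report: rate
tests compare the 20 period-level condition means per condition
(pairwise t df = 38, ANOVA df = (2, 57) at the design dimensions),
while expenditure tests pool all observations (one-sample df = 599,
ANOVA df = (2, 1797)), deliberately ignoring within-participant
dependence; the regression is the dependence-aware complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CONDITIONS
from .contest import ContestSpec, DEFAULT_SPEC, nash_equilibrium
from .panel import RandomEffectsPanelResults, re_panel_fit
from .stattests import (
    DensityCurve,
    TestResult,
    bonferroni_adjust,
    fisher_exact,
    kruskal_wallis,
    levene_test,
    mann_whitney,
    one_sample_t,
    oneway_anova,
    overbidding_rate,
    silverman_kde,
    two_sample_t,
)

__all__ = ["ContestAnalysis", "ContestAnalysisResults"]

#: Default dummy/control design of the overbidding regression.
REGRESSION_COVARIATES = ("anodal", "cathodal", "female", "age", "major", "gpa", "income")

_EQ_TOL = 1e-9  # bids within this of e* count as exact equilibrium bids


class CohortSchemaError(ValueError):
    """Cohort table does not satisfy the expected long-format schema."""


def _summary_row(values: np.ndarray) -> dict[str, float]:
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
    }


class ContestAnalysis:
    """Analysis model for a three-condition contest cohort.

    Parameters
    ----------
    cohort
        Long-format table with columns ``participant_id, condition,
        period, bid, female, age, major, gpa, income``.
    spec
        Contest constants; the equilibrium bid is derived from it.
    rate_unit
        ``"period"`` (default) computes overbidding rates from
        period-level condition means; ``"observation"`` computes a rate
        per individual bid.
    alpha
        Significance level of the Levene gate to the nonparametric branch.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        spec: ContestSpec = DEFAULT_SPEC,
        rate_unit: str = "period",
        alpha: float = 0.05,
        kde_points: int = 321,
    ) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
        if missing:
            raise CohortSchemaError(f"cohort table is missing columns: {missing}")
        if rate_unit not in ("period", "observation"):
            raise ValueError(f"rate_unit must be 'period' or 'observation', got {rate_unit!r}")
        bids = cohort["bid"].to_numpy(dtype=float)
        if np.any(~np.isfinite(bids)):
            raise CohortSchemaError("bid column contains non-finite values")
        if bids.min() < spec.min_bid or bids.max() > spec.max_bid:
            raise CohortSchemaError(
                f"bids outside [{spec.min_bid}, {spec.max_bid}] present in the table"
            )
        self.cohort = cohort.copy()
        self.spec = spec
        self.rate_unit = rate_unit
        self.alpha = alpha
        self.kde_points = kde_points
        self.conditions = tuple(
            c for c in CONDITIONS if c in set(cohort["condition"])
        ) or tuple(pd.unique(cohort["condition"]))
        self.e_star = nash_equilibrium(spec).e_star

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ContestAnalysis":
        from .cohort import read_cohort

        return cls(read_cohort(path), **kwargs)

    # ------------------------------------------------------------------

    def _rate_groups(self) -> dict[str, np.ndarray]:
        """Overbidding rates per condition at the configured unit."""
        e = self.e_star
        if self.rate_unit == "period":
            means = (
                self.cohort.groupby(["condition", "period"], sort=True)["bid"]
                .mean()
                .reset_index()
            )
            return {
                c: np.array(
                    [
                        overbidding_rate(m, e)
                        for m in means.loc[means["condition"] == c, "bid"]
                    ]
                )
                for c in self.conditions
            }
        return {
            c: np.array(
                [
                    overbidding_rate(b, e)
                    for b in self.cohort.loc[self.cohort["condition"] == c, "bid"]
                ]
            )
            for c in self.conditions
        }

    def fit(self) -> "ContestAnalysisResults":
        df = self.cohort
        e_star = self.e_star
        conds = self.conditions
        bid_groups = {
            c: df.loc[df["condition"] == c, "bid"].to_numpy(dtype=float) for c in conds
        }
        rate_groups = self._rate_groups()

        table_rates = pd.DataFrame(
            {c: _summary_row(rate_groups[c]) for c in conds}
        ).T.rename_axis("condition")
        table_bids = pd.DataFrame(
            {c: _summary_row(bid_groups[c]) for c in conds}
        ).T.rename_axis("condition")

        one_sample = {
            c: one_sample_t(values=bid_groups[c], mu0=e_star) for c in conds
        }

        anova_rate = oneway_anova([rate_groups[c] for c in conds])
        anova_bid = oneway_anova([bid_groups[c] for c in conds])

        pairs = list(combinations(conds, 2))
        pairwise_rate_t = {
            (a, b): two_sample_t(rate_groups[a], rate_groups[b]) for a, b in pairs
        }
        raw_ps = [pairwise_rate_t[p].p_value for p in pairs]
        adj = bonferroni_adjust([p if np.isfinite(p) else 1.0 for p in raw_ps])
        rate_bonferroni = dict(zip(pairs, adj))
        pairwise_bid_t = {
            (a, b): two_sample_t(bid_groups[a], bid_groups[b]) for a, b in pairs
        }
        bid_bonferroni = dict(
            zip(pairs, bonferroni_adjust([pairwise_bid_t[p].p_value for p in pairs]))
        )

        levene = levene_test([bid_groups[c] for c in conds])
        homogeneous = (not levene.ok) or levene.p_value >= self.alpha
        kruskal = mannwhitney = None
        if not homogeneous:
            kruskal = kruskal_wallis([bid_groups[c] for c in conds])
            mannwhitney = {
                (a, b): mann_whitney(bid_groups[a], bid_groups[b]) for a, b in pairs
            }

        at_eq = {c: float(np.mean(np.abs(bid_groups[c] - e_star) <= _EQ_TOL)) for c in conds}
        above_eq = {c: float(np.mean(bid_groups[c] > e_star + _EQ_TOL)) for c in conds}
        proportions = pd.DataFrame(
            {"at_equilibrium": at_eq, "above_equilibrium": above_eq}
        ).rename_axis("condition")

        def _prop_fisher(kind: str) -> dict[tuple[str, str], TestResult]:
            out = {}
            for a, b in pairs:
                na, nb = bid_groups[a].size, bid_groups[b].size
                ka = int(round(proportions.loc[a, kind] * na))
                kb = int(round(proportions.loc[b, kind] * nb))
                out[(a, b)] = fisher_exact([[ka, na - ka], [kb, nb - kb]])
            return out

        fisher_at = _prop_fisher("at_equilibrium")
        fisher_above = _prop_fisher("above_equilibrium")

        densities: dict[str, DensityCurve | None] = {}
        for c in conds:
            try:
                densities[c] = silverman_kde(
                    bid_groups[c],
                    bounds=(self.spec.min_bid, self.spec.max_bid),
                    n_grid=self.kde_points,
                )
            except ValueError:  # zero spread: no density estimate
                densities[c] = None

        reg = df.copy()
        reg["overbidding"] = reg["bid"] - e_star
        for dummy in ("anodal", "cathodal"):
            reg[dummy] = (reg["condition"] == dummy).astype(float)
        covariates = [c for c in REGRESSION_COVARIATES if c in reg.columns]
        regression = re_panel_fit(
            reg, outcome="overbidding", covariates=covariates, cluster="participant_id"
        )

        return ContestAnalysisResults(
            model=self,
            e_star=e_star,
            table_rates=table_rates,
            table_bids=table_bids,
            one_sample=one_sample,
            anova_rate=anova_rate,
            anova_bid=anova_bid,
            pairwise_rate_t=pairwise_rate_t,
            rate_bonferroni=rate_bonferroni,
            pairwise_bid_t=pairwise_bid_t,
            bid_bonferroni=bid_bonferroni,
            levene=levene,
            kruskal=kruskal,
            mannwhitney=mannwhitney,
            proportions=proportions,
            fisher_at_equilibrium=fisher_at,
            fisher_above_equilibrium=fisher_above,
            densities=densities,
            regression=regression,
        )


@dataclass
class ContestAnalysisResults:
    """Machine-readable twin of the experiment's result tables."""

    model: ContestAnalysis
    e_star: float
    table_rates: pd.DataFrame
    table_bids: pd.DataFrame
    one_sample: dict[str, TestResult]
    anova_rate: TestResult
    anova_bid: TestResult
    pairwise_rate_t: dict[tuple[str, str], TestResult]
    rate_bonferroni: dict[tuple[str, str], float]
    pairwise_bid_t: dict[tuple[str, str], TestResult]
    bid_bonferroni: dict[tuple[str, str], float]
    levene: TestResult
    kruskal: TestResult | None
    mannwhitney: dict[tuple[str, str], TestResult] | None
    proportions: pd.DataFrame
    fisher_at_equilibrium: dict[tuple[str, str], TestResult]
    fisher_above_equilibrium: dict[tuple[str, str], TestResult]
    densities: dict[str, DensityCurve | None]
    regression: RandomEffectsPanelResults
    extras: dict = field(default_factory=dict)

    # -- serialization -------------------------------------------------

    @staticmethod
    def _test_dict(t: TestResult | None) -> dict | None:
        if t is None:
            return None
        return {
            "method": t.method,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "extras": {k: v for k, v in t.extras.items() if not isinstance(v, np.ndarray)},
            "error": t.error,
        }

    def to_dict(self) -> dict:
        pair_key = lambda p: f"{p[0]}_vs_{p[1]}"
        return {
            "e_star": self.e_star,
            "table_rates": self.table_rates.to_dict(orient="index"),
            "table_bids": self.table_bids.to_dict(orient="index"),
            "one_sample_t": {c: self._test_dict(t) for c, t in self.one_sample.items()},
            "anova_rate": self._test_dict(self.anova_rate),
            "anova_bid": self._test_dict(self.anova_bid),
            "pairwise_rate_t": {
                pair_key(p): self._test_dict(t) for p, t in self.pairwise_rate_t.items()
            },
            "rate_bonferroni": {pair_key(p): v for p, v in self.rate_bonferroni.items()},
            "pairwise_bid_t": {
                pair_key(p): self._test_dict(t) for p, t in self.pairwise_bid_t.items()
            },
            "bid_bonferroni": {pair_key(p): v for p, v in self.bid_bonferroni.items()},
            "levene": self._test_dict(self.levene),
            "kruskal_wallis": self._test_dict(self.kruskal),
            "mann_whitney": None
            if self.mannwhitney is None
            else {pair_key(p): self._test_dict(t) for p, t in self.mannwhitney.items()},
            "proportions": self.proportions.to_dict(orient="index"),
            "fisher_at_equilibrium": {
                pair_key(p): self._test_dict(t)
                for p, t in self.fisher_at_equilibrium.items()
            },
            "fisher_above_equilibrium": {
                pair_key(p): self._test_dict(t)
                for p, t in self.fisher_above_equilibrium.items()
            },
            "regression": {
                "params": self.regression.params.to_dict(),
                "cluster_se": self.regression.bse.to_dict(),
                "p_values": self.regression.pvalues.to_dict(),
                "sigma_u2": self.regression.sigma_u2,
                "sigma_eps2": self.regression.sigma_eps2,
                "theta_mean": float(self.regression.theta.mean()),
                "nobs": self.regression.nobs,
                "n_clusters": self.regression.n_groups,
            },
            "kde_bandwidths": {
                c: (None if d is None else d.bandwidth)
                for c, d in self.densities.items()
            },
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write results.json, the two summary tables, the regression
        table, and one density CSV per condition."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        results_path = outdir / "results.json"
        results_path.write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")
        paths["results"] = results_path
        t1 = outdir / "table1.csv"
        self.table_rates.round(3).to_csv(t1)
        paths["table1"] = t1
        t2 = outdir / "table2.csv"
        self.table_bids.round(3).to_csv(t2)
        paths["table2"] = t2
        t3 = outdir / "table3.csv"
        pd.DataFrame(
            {
                "coef": self.regression.params,
                "cluster_se": self.regression.bse,
                "t": self.regression.tvalues,
                "p": self.regression.pvalues,
            }
        ).to_csv(t3)
        paths["table3"] = t3
        for c, d in self.densities.items():
            if d is None:
                continue
            p = outdir / f"density_{c}.csv"
            pd.DataFrame({"bid": d.grid, "density": d.density}).to_csv(p, index=False)
            paths[f"density_{c}"] = p
        return paths

    def summary(self) -> str:
        lines = [
            "Proportional-prize contest: overbidding analysis",
            "=" * 56,
            f"Equilibrium bid e* = {self.e_star:g} francs",
            "",
            "Overbidding rates (period-level condition means):"
            if self.model.rate_unit == "period"
            else "Overbidding rates (per observation):",
            self.table_rates.round(3).to_string(),
            "",
            "Individual expenditures (francs):",
            self.table_bids.round(3).to_string(),
            "",
            "One-sample t vs. equilibrium:",
        ]
        for c, t in self.one_sample.items():
            lines.append(f"  {c:9s} {t}")
        lines += [
            "",
            f"Rate ANOVA:        {self.anova_rate}",
            f"Expenditure ANOVA: {self.anova_bid}",
            f"Levene gate:       {self.levene}",
        ]
        if self.kruskal is not None:
            lines.append(f"Kruskal-Wallis:    {self.kruskal}")
            for p, t in (self.mannwhitney or {}).items():
                z = t.extras.get("z", float("nan"))
                lines.append(
                    f"  MW {p[0]} vs {p[1]}: z={z:.3f}, p={t.p_value:.4g}"
                )
        lines += [
            "",
            "Bid proportions:",
            self.proportions.round(4).to_string(),
            "",
            self.regression.summary(),
        ]
        return "\n".join(lines)
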