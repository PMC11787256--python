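"""Summary report: cohort table, association table, forest and volcano plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["make_report"]

_REQUIRED = ["covariates.csv", "ahei_scores.csv", "composition.csv",
             "associations_primary.tsv"]


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ({x.std():.1f})"


def _median_iqr(x: pd.Series) -> str:
    q1, q3 = x.quantile([0.25, 0.75])
    return f"{x.median():.1f} [{q1:.1f}, {q3:.1f}]"


def _n_pct(x: pd.Series) -> str:
    n = int(x.sum())
    return f"{n} ({100 * n / len(x):.1f})"


def cohort_table(covariates: pd.DataFrame, scores: pd.DataFrame,
                 composition: pd.DataFrame, intakes: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """Cohort-characteristics table: mean (SD), median [IQR], or n (%)."""
    rows = {
        "Age (yrs)": _mean_sd(covariates["age"]),
        "College Graduate or More": _n_pct(covariates["college_grad"]),
        "Pre-Pregnancy BMI (kg/m2)": _mean_sd(covariates["pre_preg_bmi"]),
        "AHEI-2010 Score (0-110)": _mean_sd(scores["ahei_total"]),
        "Vigorous Physical Activity (hrs/wk)": _median_iqr(
            covariates["vigorous_activity_hrs_wk"].dropna()),
        "Gestational Age at Blood Collection (wks)": _mean_sd(
            covariates["gest_age_weeks"]),
        "Afternoon Blood Collection": _n_pct(covariates["afternoon_draw"]),
        "Total EVP miRNA Counts": _median_iqr(composition["total_counts"]),
        "Sample Richness": _mean_sd(composition["richness"]),
        "Sample Evenness (0-1)": _mean_sd(composition["evenness"].dropna()),
    }
    if intakes is not None and "kcal_per_day" in intakes.columns:
        rows["Total Caloric Intake (kcal/day)"] = _mean_sd(intakes["kcal_per_day"])
    return pd.DataFrame({"Characteristic": rows.keys(), "Value": rows.values()})


def _forest_plot(components: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    y = np.arange(len(components))[::-1]
    ax.errorbar(components["estimate"], y,
                xerr=[components["estimate"] - components["ci_low"],
                      components["ci_high"] - components["estimate"]],
                fmt="o", color="tab:blue", ecolor="gray", capsize=3)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(components["exposure"])
    ax.set_xlabel("Effect on sample richness per component-score point (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _volcano_plot(mirna: pd.DataFrame, path: Path, alpha: float = 0.05) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(mirna["p"].astype(float))
    sig = mirna["q"] < alpha
    ax.scatter(mirna["estimate"], neglog, s=12,
               c=np.where(sig, "red", "silver"))
    for _, row in mirna[sig].iterrows():
        ax.annotate(row["outcome"], (row["estimate"], -np.log10(row["p"])),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    m = max(len(mirna), 1)
    ax.axhline(-np.log10(0.01 / m), color="red", lw=0.8, ls="--")
    ax.set_xlabel("Effect estimate per exposure unit")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def make_report(results_dir, alpha: float = 0.05) -> Path:
    """Assemble report.md plus figures from a completed run directory.

    Raises if required result tables are missing, listing them.
    """
    results_dir = Path(results_dir)
    missing = [f for f in _REQUIRED if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing result tables: {missing}")

    covariates = pd.read_csv(results_dir / "covariates.csv",
                             index_col="participant_id")
    scores = pd.read_csv(results_dir / "ahei_scores.csv", index_col=0)
    comp = pd.read_csv(results_dir / "composition.csv", index_col="sample_id")
    intakes_path = results_dir / "intakes.csv"
    intakes = (pd.read_csv(intakes_path, index_col="participant_id")
               if intakes_path.exists() else None)
    primary = pd.read_csv(results_dir / "associations_primary.tsv", sep="\t")

    table1 = cohort_table(covariates, scores, comp, intakes)
    table1.to_csv(results_dir / "table1.csv", index=False)

    table2 = primary[["outcome", "estimate", "ci_low", "ci_high", "p"]].copy()
    table2["effect (95% CI)"] = [
        f"{r.estimate:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})"
        for r in table2.itertuples()
    ]
    table2 = table2[["outcome", "effect (95% CI)", "p"]]
    table2.to_csv(results_dir / "table2.csv", index=False)

    lines = ["# Pipeline report", "", "## Cohort characteristics", "",
             table1.to_markdown(index=False), "",
             "## AHEI-2010 vs miRNA composition (robust linear models)", "",
             table2.to_markdown(index=False), ""]

    comp_path = results_dir / "associations_components.tsv"
    if comp_path.exists():
        components = pd.read_csv(comp_path, sep="\t")
        if len(components):
            _forest_plot(components, results_dir / "fig_forest.png")
            lines += ["## Component scores vs richness", "",
                      "![forest](fig_forest.png)", ""]

    mirna_path = results_dir / "associations_mirna.tsv"
    if mirna_path.exists():
        mirna = pd.read_csv(mirna_path, sep="\t")
        for stratum in ("continuous", "binary"):
            sub = mirna[mirna["stratum"] == stratum]
            if len(sub):
                fig = results_dir / f"fig_volcano_{stratum}.png"
                _volcano_plot(sub, fig, alpha=alpha)
                lines += [f"## Per-miRNA associations ({stratum} stratum)", "",
                          f"![volcano]({fig.name})", ""]

    out = results_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
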