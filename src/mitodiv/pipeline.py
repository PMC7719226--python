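"""End-to-end analysis: traits, contrasts, regressions, consistency, report.

Mirrors the workflow of a comparative mtDNA diversity study: derive
mass-specific metabolic rate and the composite census-size proxy, test
each trait for phylogenetic signal, correlate contrasts of log piS and
log piN/piS with each life-history trait, fit the multiple-regression
recipe (drop longevity, never pair mass with MSMR), and compare the
observed piN/piS slope with the gamma-DFE prediction -gamma*beta.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association, comparative, dfe_consistency, seq_diversity, sister_pairs
from .comparative import Phylogeny
from .seq_diversity import CodonAlignment

logger = logging.getLogger(__name__)

#: traits considered against the two molecular statistics, in report order
LIFE_HISTORY_TRAITS = [
    "mass_g",
    "longevity_months",
    "maturity_days",
    "msmr",
    "range_km2",
    "abs_latitude",
    "composite_n",
]

RESPONSES = ["pi_s", "pi_n_over_pi_s"]


@dataclass
class AnalysisConfig:
    """Inputs and knobs of one pipeline run."""

    manifest: Path | None = None
    tree: Path | None = None
    traits: Path | None = None
    outdir: Path = Path("results")
    min_individuals: int = seq_diversity.MIN_INDIVIDUALS
    beta: float = dfe_consistency.DEFAULT_BETA
    seed: int = 0
    triplet_dir: Path | None = None
    ds_require_both: bool = True


def normalize_name(name: str) -> str:
    """Exact-string species matching after whitespace/underscore folding."""
    return re.sub(r"[\s_]+", "_", name.strip())


def derive_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Add msmr, abs_latitude and the composite census-size proxy.

    msmr = basal metabolic rate (ml O2/h) / measurement mass (g); the
    composite proxy is range/(msmr*mass) = range/BMR.  Species lacking
    an input, or with non-positive mass/BMR, get NaN in the derived
    column and are logged.
    """
    out = raw.copy()
    if "msmr" not in out.columns:
        out["msmr"] = np.nan
    if {"bmr_ml_o2_h", "mass_g"} <= set(out.columns):
        mass = out["mass_g"]
        bmr = out["bmr_ml_o2_h"]
        ok = (mass > 0) & (bmr > 0)
        derived = bmr.where(ok) / mass.where(ok)
        out["msmr"] = out["msmr"].fillna(derived)
        n_bad = int((~ok & bmr.notna()).sum())
        if n_bad:
            logger.warning("%d species with non-positive mass/BMR flagged", n_bad)
    if "latitude" in out.columns:
        out["abs_latitude"] = out["latitude"].abs()
    ok = (
        out.get("range_km2", pd.Series(np.nan, index=out.index)) > 0
    ) & (out["msmr"] > 0) & (out.get("mass_g") > 0)
    out["composite_n"] = np.where(
        ok, out["range_km2"] / (out["msmr"] * out["mass_g"]), np.nan
    )
    missing = int((~ok).sum())
    if missing:
        logger.info("%d species lack inputs for the composite measure", missing)
    return out


@dataclass
class AnalysisResult:
    """All tables produced by one run, plus the machine-readable report."""

    diversity: pd.DataFrame
    lambda_table: pd.DataFrame
    correlations: pd.DataFrame
    regression_report: dict
    consistency: dict
    exclusions: pd.DataFrame
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)
    triplets: pd.DataFrame | None = None
    triplet_contrasts: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "lambda": self.lambda_table.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "regression": self.regression_report,
            "consistency": self.consistency,
            "n_species": int(len(self.diversity)),
            "exclusions": self.exclusions.to_dict(orient="records"),
        }
        if self.triplets is not None:
            out["triplets"] = self.triplets.to_dict(orient="records")
        return out


def _merged_table(
    diversity: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join diversity and traits on normalized names; report mismatches."""
    div = diversity.copy()
    div.index = [normalize_name(s) for s in div["species"]]
    tr = traits.copy()
    tr.index = [normalize_name(str(s)) for s in tr.index]
    common = div.index.intersection(tr.index)
    mismatch_rows = [
        {"species": s, "reason": "name-mismatch (diversity only)"}
        for s in div.index.difference(tr.index)
    ] + [
        {"species": s, "reason": "name-mismatch (traits only)"}
        for s in tr.index.difference(div.index)
    ]
    merged = tr.loc[common].join(
        div.loc[common, ["pi_s", "pi_n", "pi_n_over_pi_s", "n_individuals"]]
    )
    return merged, pd.DataFrame(mismatch_rows, columns=["species", "reason"])


def run_analysis(
    alignments: Mapping[str, CodonAlignment],
    traits: pd.DataFrame,
    phylo: Phylogeny,
    config: AnalysisConfig | None = None,
    triplet_alignments: Sequence[CodonAlignment] | None = None,
    triplet_traits: pd.DataFrame | None = None,
) -> AnalysisResult:
    """The full comparative analysis on in-memory inputs.

    Deterministic given its inputs; the only randomness in the project
    lives in the synthetic-data generator.
    """
    config = config or AnalysisConfig()
    div_table, excl = seq_diversity.diversity_table(
        alignments.values(), min_individuals=config.min_individuals
    )
    ratio_excl = pd.DataFrame(
        [
            {"species": sp, "reason": "zero-piS-for-ratio"}
            for sp, v in zip(div_table["species"], div_table["pi_n_over_pi_s"])
            if not np.isfinite(v)
        ],
        columns=["species", "reason"],
    )
    traits = derive_traits(traits)
    merged, mismatches = _merged_table(div_table, traits)
    exclusions = pd.concat([excl, ratio_excl, mismatches], ignore_index=True)

    tip_names = {normalize_name(lb): lb for lb in phylo.tip_labels}
    merged = merged.loc[[s for s in merged.index if s in tip_names]]
    merged.index = [tip_names[s] for s in merged.index]

    lambda_rows = []
    for trait in RESPONSES + [t for t in LIFE_HISTORY_TRAITS
                              if t in merged.columns]:
        series = merged[trait].dropna()
        series = series[series > 0]
        if len(series) < 4:
            continue
        fit = comparative.pagel_lambda(phylo, series, log_transform=True)
        lambda_rows.append(
            {"trait": trait, "lambda": fit.lambda_hat, "p": fit.lrt_p,
             "n": fit.n_tips}
        )
    lambda_table = pd.DataFrame(lambda_rows, columns=["trait", "lambda", "p", "n"])

    corr_rows = []
    contrast_cache: dict[str, pd.DataFrame] = {}
    for trait in LIFE_HISTORY_TRAITS:
        if trait not in merged.columns:
            continue
        for response in RESPONSES:
            try:
                cf = comparative.contrast_frame(
                    phylo, merged, [trait, response], log_transform=True
                )
            except comparative.TreeError:
                continue
            contrast_cache[f"{response}~{trait}"] = cf
            cor = association.contrast_correlation(cf[trait], cf[response])
            slope_fit = association.origin_regression(
                cf[response], cf[[trait]], response=response
            )
            corr_rows.append(
                {
                    "trait": trait,
                    "response": response,
                    "n": cor.n,
                    "r": cor.r,
                    "slope": float(slope_fit.slopes[trait]),
                    "p": cor.p,
                }
            )
    correlations = pd.DataFrame(
        corr_rows, columns=["trait", "response", "n", "r", "slope", "p"]
    )

    regression_report = _regression_recipe(phylo, merged)
    consistency = _consistency_section(correlations, config.beta)

    result = AnalysisResult(
        diversity=div_table,
        lambda_table=lambda_table,
        correlations=correlations,
        regression_report=regression_report,
        consistency=consistency,
        exclusions=exclusions,
        contrasts=contrast_cache,
    )
    if triplet_alignments:
        result.triplets, result.triplet_contrasts = _triplet_section(
            triplet_alignments, triplet_traits, config
        )
    return result


def _regression_recipe(phylo: Phylogeny, merged: pd.DataFrame) -> dict:
    """The scripted model-selection path for piS.

    Longevity is dropped for collinearity with age at maturity; mass and
    MSMR are never included together (their log contrasts are strongly
    negatively correlated, inflating variance); age at maturity and
    latitude are tested as additions to range + MSMR by nested F tests.
    """
    report: dict = {}
    base_predictors = ["range_km2", "msmr"]
    try:
        cf = comparative.contrast_frame(
            phylo, merged, base_predictors + ["pi_s"], log_transform=True
        )
    except comparative.TreeError as exc:
        return {"error": str(exc)}
    fit = association.origin_regression(
        cf["pi_s"], cf[base_predictors], response="pi_s"
    )
    report["pi_s_model"] = {
        "predictors": base_predictors,
        "slopes": {k: float(v) for k, v in fit.slopes.items()},
        "p_values": {k: float(v) for k, v in fit.p_values.items()},
        "adj_r_squared": fit.adj_r_squared,
        "n": fit.n,
    }
    # collinearity screen mass vs MSMR
    try:
        cf_mm = comparative.contrast_frame(
            phylo, merged, ["mass_g", "msmr"], log_transform=True
        )
        vifs = association.vif(cf_mm)
        cor_mm = association.contrast_correlation(cf_mm["mass_g"], cf_mm["msmr"])
        report["mass_msmr_screen"] = {
            "r": cor_mm.r,
            "vif": {k: float(v) for k, v in vifs.items()},
            "n": cor_mm.n,
        }
    except (comparative.TreeError, ValueError):
        pass
    # nested additions
    for extra in ["maturity_days", "abs_latitude"]:
        if extra not in merged.columns:
            continue
        try:
            cf_x = comparative.contrast_frame(
                phylo, merged, base_predictors + [extra, "pi_s"],
                log_transform=True,
            )
        except comparative.TreeError:
            continue
        small = association.origin_regression(
            cf_x["pi_s"], cf_x[base_predictors], response="pi_s"
        )
        full = association.origin_regression(
            cf_x["pi_s"], cf_x[base_predictors + [extra]], response="pi_s"
        )
        report.setdefault("nested_tests", {})[extra] = {
            "p": association.nested_f_test(small, full),
            "n": small.n,
        }
    # piN/piS multiple regression with the same predictors
    try:
        cf_r = comparative.contrast_frame(
            phylo, merged, base_predictors + ["pi_n_over_pi_s"],
            log_transform=True,
        )
        fit_r = association.origin_regression(
            cf_r["pi_n_over_pi_s"], cf_r[base_predictors],
            response="pi_n_over_pi_s",
        )
        report["ratio_model"] = {
            "predictors": base_predictors,
            "slopes": {k: float(v) for k, v in fit_r.slopes.items()},
            "p_values": {k: float(v) for k, v in fit_r.p_values.items()},
            "adj_r_squared": fit_r.adj_r_squared,
            "n": fit_r.n,
        }
    except (comparative.TreeError, ValueError):
        pass
    return report


def _consistency_section(correlations: pd.DataFrame, beta: float) -> dict:
    """Observed vs gamma-DFE-predicted slopes, with doubling effects."""
    out: dict = {"beta": beta, "by_trait": {}}
    for trait in ["range_km2", "msmr", "composite_n"]:
        sel_s = correlations.query(
            "trait == @trait and response == 'pi_s'"
        )
        sel_r = correlations.query(
            "trait == @trait and response == 'pi_n_over_pi_s'"
        )
        if sel_s.empty:
            continue
        gamma_hat = float(sel_s["slope"].iloc[0])
        pred = dfe_consistency.predicted_slope(gamma_hat, beta)
        entry = {
            "gamma_hat": gamma_hat,
            "predicted_ratio_slope": pred.predicted_slope,
            "pi_s_doubling_percent": dfe_consistency.doubling_effect(gamma_hat),
        }
        if not sel_r.empty:
            entry["observed_ratio_slope"] = float(sel_r["slope"].iloc[0])
        out["by_trait"][trait] = entry
    return out


def _triplet_section(
    triplet_alignments: Sequence[CodonAlignment],
    triplet_traits: pd.DataFrame | None,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sister dS, the retention filter, and pair contrasts."""
    records = []
    for aln in triplet_alignments:
        ds1, ds2 = sister_pairs.triplet_branch_ds(aln)
        sp1, sp2, outg = aln.sequence_ids
        trip = sister_pairs.Triplet(
            sp1=sp1, sp2=sp2, outgroup=outg, shared_gene=aln.genes[0][0]
        )
        rec = sister_pairs.TripletRecord(triplet=trip, ds1=ds1, ds2=ds2)
        if triplet_traits is not None:
            for sp, store in [(sp1, rec.traits1), (sp2, rec.traits2)]:
                if sp in triplet_traits.index:
                    store.update(triplet_traits.loc[sp].to_dict())
        records.append(rec)
    sister_pairs.filter_ds(records, require_both=config.ds_require_both)
    return (
        sister_pairs.triplet_table(records),
        sister_pairs.contrast_table(records),
    )


def world_slopes(world) -> dict:
    """Key contrast-regression slopes of one synthetic world.

    Runs diversity estimation over every species, takes independent
    contrasts of the log-transformed variables, and fits through-origin
    regressions: gamma_hat (log piS on log range) and the log piN/piS
    on log range slope the gamma-DFE model predicts to be
    -gamma_true*beta_true.
    """
    table, _ = seq_diversity.diversity_table(world.alignments.values())
    merged = world.traits.copy()
    div = table.set_index("species")
    merged["pi_s"] = div["pi_s"]
    merged["pi_n_over_pi_s"] = div["pi_n_over_pi_s"]
    out = {}
    cf_s = comparative.contrast_frame(
        world.phylogeny, merged, ["range_km2", "pi_s"], log_transform=True
    )
    out["gamma_hat"] = float(
        association.origin_regression(cf_s["pi_s"], cf_s[["range_km2"]])
        .slopes.iloc[0]
    )
    cf_r = comparative.contrast_frame(
        world.phylogeny, merged, ["range_km2", "pi_n_over_pi_s"],
        log_transform=True,
    )
    out["ratio_slope"] = float(
        association.origin_regression(
            cf_r["pi_n_over_pi_s"], cf_r[["range_km2"]]
        ).slopes.iloc[0]
    )
    out["n_ratio_contrasts"] = int(len(cf_r))
    return out


# ---------------------------------------------------------------------------
# File-based entry points and report rendering
# ---------------------------------------------------------------------------

def load_inputs(
    config: AnalysisConfig,
) -> tuple[dict[str, CodonAlignment], pd.DataFrame, Phylogeny]:
    """Read the manifest/FASTA, trait TSV and Newick tree from disk."""
    if config.manifest is None or config.tree is None or config.traits is None:
        raise ValueError("manifest, tree and traits paths are all required")
    manifest = pd.read_csv(config.manifest, sep="\t")
    root = Path(config.manifest).parent
    alignments: dict[str, CodonAlignment] = {}
    for species, group in manifest.groupby("species"):
        parts = [
            seq_diversity.read_alignment_file(
                root / row["file"], species_id=str(species), gene=row["gene"]
            )
            for _, row in group.iterrows()
        ]
        alignments[str(species)] = seq_diversity.concatenate_genes(parts)
    traits = pd.read_csv(config.traits, sep="\t", index_col=0)
    phylo = comparative.read_newick(Path(config.tree).read_text())
    return alignments, traits, phylo


def write_report(result: AnalysisResult, outdir: str | Path) -> None:
    """Emit TSV tables, a Markdown report and a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    result.lambda_table.to_csv(outdir / "lambda.tsv", sep="\t", index=False)
    result.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    result.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    for key, cf in result.contrasts.items():
        safe = key.replace("~", "_on_")
        cf.to_csv(outdir / f"contrasts_{safe}.tsv", sep="\t")
    if result.triplets is not None:
        result.triplets.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    if result.triplet_contrasts is not None:
        result.triplet_contrasts.to_csv(
            outdir / "triplet_contrasts.tsv", sep="\t", index=False
        )
    (outdir / "report.json").write_text(
        json.dumps(result.to_json_dict(), indent=2, default=float)
    )
    (outdir / "report.md").write_text(render_markdown(result))


def render_markdown(result: AnalysisResult) -> str:
    lines = ["# Mitochondrial diversity analysis report", ""]
    lines += ["## Phylogenetic signal (Pagel's lambda, log-transformed traits)", ""]
    lines.append(result.lambda_table.to_markdown(index=False))
    lines += ["", "## Contrast correlations (through the origin)", ""]
    lines.append(result.correlations.to_markdown(index=False))
    lines += ["", "## Multiple regression recipe", "",
              "```json", json.dumps(result.regression_report, indent=2,
                                    default=float), "```"]
    cons = result.consistency
    lines += ["", f"## DFE consistency (beta = {cons['beta']})", ""]
    for trait, entry in cons["by_trait"].items():
        obs = entry.get("observed_ratio_slope")
        obs_txt = f"{obs:+.3f}" if obs is not None else "n/a"
        lines.append(
            f"- {trait}: gamma_hat = {entry['gamma_hat']:+.3f}; predicted "
            f"piN/piS slope = {entry['predicted_ratio_slope']:+.3f}; observed "
            f"= {obs_txt}; piS changes by "
            f"{entry['pi_s_doubling_percent']:+.0f}% per doubling"
        )
    lines += ["", "## Exclusions", "",
              f"{len(result.exclusions)} species-level exclusions "
              "(see exclusions.tsv); raw p values are reported throughout, "
              "with no multiple-testing correction."]
    if result.triplets is not None:
        kept = int(result.triplets["retained"].sum())
        lines += ["", "## Sister-triplet divergence", "",
                  f"{kept} of {len(result.triplets)} triplets retained by the "
                  "dS window (see triplets.tsv)."]
    return "\n".join(lines) + "\n"
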