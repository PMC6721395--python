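"""Orchestration of the full comparative analysis.

``run_full_analysis`` drives, from one :class:`RunConfig`: the Mk
ER-vs-ARD test and stochastic-map transition counting on the binary
learning state; phylogenetic ANOVAs (binary and ternary codings) with a
Holm correction across the seven-trait family; lambda-PGLS of each trait
against the continuous learning window; Brownie ensemble rate tests
under the two-rate, three-rate and shorter/longer-learning groupings;
Pagel threshold sweeps over the song traits; and repeated-run Pagel
tests against the binary mating traits.  ``jackknife`` repeats a scoped
subset of these analyses leaving out one family (or one species) at a
time and flags results whose significance status flips.

Reproducibility: the master seed is mapped to per-stage seeds by stable
hashing of stage identifiers, so adding a stage never perturbs the
draws of another, and rerunning any stage with the same inputs is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import comp_stats, mk_ctmc, pagel_sweep, rate_models
from .phylo_core import Phylogeny, linearize, parse_newick, prune_to_taxa
from .synthetic_data import SyntheticConfig, generate_study_dataset
from .trait_model import (
    SONG_TRAITS,
    AnalysisDataset,
    build_analysis_dataset,
    records_from_csv,
)

__all__ = ["RunConfig", "stage_seed", "load_dataset", "run_full_analysis", "jackknife"]

#: Traits with enough early song-stable species for the ternary analyses.
TERNARY_TRAITS = ("syllable_repertoire", "song_repertoire", "syllables_per_song")


@dataclass
class RunConfig:
    """Knobs of one full analysis run.

    Either ``tree_path`` and ``traits_path`` point at data files, or
    ``synthetic`` supplies a generator configuration.  The default
    numeric knobs are the full-scale settings (10,000 maps for
    transition counting, 1,300 for the Brownie ensemble, 1,000 ANOVA
    simulations, 100 sweep runs per threshold, 1,000 runs for the
    mating traits); ``fast=True`` switches to the reduced test profile
    (100 / 100 / 200 / 10 / 50).
    """

    tree_path: str | None = None
    traits_path: str | None = None
    synthetic: SyntheticConfig | None = None
    aggregation: str = "median"
    seed: int = 0
    outdir: str | None = None
    fast: bool = False
    melospiza_override: bool = False
    improviser_species: str | None = None
    n_maps: int = 10_000
    n_maps_brownie: int = 1_300
    n_sim_anova: int = 1_000
    runs_per_threshold: int = 100
    runs_binary: int = 1_000
    n_bins: int = 3
    restarts: int = 10
    sweep_traits: tuple = ("syllable_repertoire", "song_repertoire")
    analyses: tuple = ("asr", "phylanova", "pgls", "brownie", "pagel", "mating")

    def resolved(self) -> "RunConfig":
        if not self.fast:
            return self
        import dataclasses

        return dataclasses.replace(
            self,
            n_maps=100,
            n_maps_brownie=100,
            n_sim_anova=200,
            runs_per_threshold=10,
            runs_binary=50,
            restarts=5,
        )

    def content_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def load_dataset(config: RunConfig) -> AnalysisDataset:
    if config.synthetic is not None:
        ds = generate_study_dataset(config.synthetic)
        tree, records = ds.tree, ds.records
    else:
        if not config.tree_path or not config.traits_path:
            raise ValueError("need tree_path and traits_path or a synthetic config")
        tree = parse_newick(Path(config.tree_path).read_text())
        records = records_from_csv(config.traits_path)
    return build_analysis_dataset(
        records,
        tree,
        aggregation=config.aggregation,
        melospiza_override=config.melospiza_override,
        improviser_species=config.improviser_species,
    )


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _asr_stage(data: AnalysisDataset, cfg: RunConfig) -> dict:
    learn = data.labels("learning_binary")
    ta = linearize(data.tree)
    lrt = mk_ctmc.lrt_er_vs_ard(
        ta, learn, restarts=cfg.restarts, seed=stage_seed(cfg.seed, "asr-fit")
    )
    maps = mk_ctmc.sample_stochastic_maps(
        ta, learn, lrt["er"], cfg.n_maps, seed=stage_seed(cfg.seed, "asr-maps")
    )
    mins = mk_ctmc.minimum_transitions(maps)
    marg = mk_ctmc.ancestral_marginals(ta, learn, lrt["er"])
    return {
        "ll_er": lrt["er"].log_likelihood,
        "ll_ard": lrt["ard"].log_likelihood,
        "er_rate": float(lrt["er"].rates[0]),
        "lrt_p": lrt["p_value"],
        "lrt_df": lrt["df"],
        "n_maps": cfg.n_maps,
        "min_transitions": mins["minimum"],
        "mean_transitions": mins["mean"],
        "directed_counts_argmin": mins["directed_counts"].tolist(),
        "states": list(lrt["er"].model.states),
        "ancestral_marginals": {str(k): v.tolist() for k, v in marg.items()},
        "_fit": lrt["er"],
        "_maps": maps,
    }


def _phylanova_stage(
    data: AnalysisDataset, cfg: RunConfig, coding: str = "learning_binary"
) -> pd.DataFrame:
    traits = SONG_TRAITS if coding == "learning_binary" else TERNARY_TRAITS
    groups = data.labels(coding)
    rows = []
    posthoc_rows = []
    for trait in traits:
        vals = data.trait_values(trait)
        common = [s for s in vals if s in groups]
        if len({groups[s] for s in common}) < 2:
            continue
        res = comp_stats.phyl_anova(
            data.tree,
            vals,
            groups,
            n_sim=cfg.n_sim_anova,
            seed=stage_seed(cfg.seed, f"phylanova-{coding}-{trait}"),
        )
        row = {"trait": trait, "F": res.f_observed, "p": res.p_value, "n": len(common)}
        for g, m in res.group_means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
        for (g1, g2), t in res.posthoc_t.items():
            posthoc_rows.append(
                {
                    "trait": trait,
                    "state_1": g1,
                    "state_2": g2,
                    "T": t,
                    "p": res.posthoc_p[(g1, g2)],
                }
            )
    df = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    hol = comp_stats.holm(df["p"].to_numpy())
    df["corrected_alpha"] = hol.thresholds
    df["significant"] = hol.reject
    df.attrs["posthoc"] = pd.DataFrame(posthoc_rows)
    return df


def _pgls_stage(data: AnalysisDataset, cfg: RunConfig) -> pd.DataFrame:
    years = data.labels("learning_years")
    rows = []
    for trait in SONG_TRAITS:
        vals = data.trait_values(trait)
        fit = comp_stats.fit_pgls(data.tree, vals, years)
        rows.append(
            {
                "trait": trait,
                "slope": fit.slope,
                "std_error": fit.std_error,
                "lambda": fit.lam,
                "T": fit.t_value,
                "p": fit.p_value,
                "n": fit.n,
            }
        )
    df = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    hol = comp_stats.holm(df["p"].to_numpy())
    df["corrected_alpha"] = hol.thresholds
    df["significant"] = hol.reject
    return df


def _brownie_one(
    data: AnalysisDataset,
    cfg: RunConfig,
    trait: str,
    coding: str,
    groupings: dict[str, dict],
    stage: str,
) -> dict:
    """Ensemble fits of one trait under several nested regime groupings.

    Maps are sampled on the tree pruned to species with both the trait
    and the coding, from an ER generator fitted to the full coding data
    (the transition rates come from all species, as in the source
    workflow).
    """
    states_all = data.labels(coding)
    vals = data.trait_values(trait)
    labels = [s for s in vals if s in states_all]
    ta_full = linearize(data.tree)
    fit = mk_ctmc.fit_mk(
        ta_full,
        states_all,
        "ER",
        restarts=cfg.restarts,
        seed=stage_seed(cfg.seed, f"{stage}-q"),
    )
    sub_tree = prune_to_taxa(data.tree, set(labels))
    ta = linearize(sub_tree)
    sub_states = {s: states_all[s] for s in labels}
    maps = mk_ctmc.sample_stochastic_maps(
        ta, sub_states, fit, cfg.n_maps_brownie,
        seed=stage_seed(cfg.seed, f"{stage}-maps"),
    )
    out: dict[str, rate_models.EnsembleRateTest] = {}
    for name, grouping in groupings.items():
        out[name] = rate_models.ensemble_rate_test(
            ta, vals, maps, grouping,
            seed=stage_seed(cfg.seed, f"{stage}-{name}"),
        )
    return out


def _brownie_stage(data: AnalysisDataset, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    results: dict[str, pd.DataFrame] = {}
    # binary two-rate vs one-rate, all seven traits (Table 5 shape)
    rows = []
    for trait in SONG_TRAITS:
        fits = _brownie_one(
            data, cfg, trait, "learning_binary",
            {"two": {"stable": "stable", "plastic": "plastic"}},
            f"brownie2-{trait}",
        )
        t = fits["two"]
        rows.append(
            {
                "trait": trait,
                "one_rate": t.ll_simple,
                "two_rates": t.ll_complex_mean,
                "p": t.p_value,
            }
        )
    results["binary_two_rate"] = (
        pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    )

    # ternary groupings for the repertoire traits (Tables 6-9 shape)
    rows6, rows7, rows8, rows9 = [], [], [], []
    for trait in TERNARY_TRAITS:
        fits = _brownie_one(
            data, cfg, trait, "learning_ternary",
            {
                "three": {"early": "early", "delayed": "delayed", "plastic": "plastic"},
                "stable_plastic": {
                    "early": "stable", "delayed": "stable", "plastic": "plastic"
                },
                "shorter_longer": {
                    "early": "shorter", "delayed": "longer", "plastic": "longer"
                },
            },
            f"brownie3-{trait}",
        )
        three, two_sp, two_sl = (
            fits["three"], fits["stable_plastic"], fits["shorter_longer"]
        )
        rows6.append(
            {
                "trait": trait,
                "one_rate": three.ll_simple,
                "three_rates": three.ll_complex_mean,
                "p": three.p_value,
            }
        )
        rows7.append(
            {
                "trait": trait,
                "two_rates": two_sp.ll_complex_mean,
                "three_rates": three.ll_complex_mean,
                "p": rate_models.chi_square_compare(
                    two_sp.ll_complex_mean, three.ll_complex_mean, 1
                ),
            }
        )
        rows8.append(
            {
                "trait": trait,
                "one_rate": two_sl.ll_simple,
                "two_rates": two_sl.ll_complex_mean,
                "p": two_sl.p_value,
            }
        )
        rows9.append(
            {
                "trait": trait,
                "two_rates": two_sl.ll_complex_mean,
                "three_rates": three.ll_complex_mean,
                "p": rate_models.chi_square_compare(
                    two_sl.ll_complex_mean, three.ll_complex_mean, 1
                ),
            }
        )
    for key, rows_ in (
        ("ternary_three_rate", rows6),
        ("two_vs_three", rows7),
        ("shorter_longer", rows8),
        ("shorter_longer_vs_three", rows9),
    ):
        results[key] = pd.DataFrame(rows_).sort_values("p").reset_index(drop=True)
    return results


def _pagel_stage(data: AnalysisDataset, cfg: RunConfig) -> dict:
    learn = data.labels("learning_binary")
    out = {}
    for trait in cfg.sweep_traits:
        vals = data.trait_values(trait)
        sweep = pagel_sweep.threshold_sweep(
            data.tree,
            learn,
            vals,
            runs_per_threshold=cfg.runs_per_threshold,
            seed=stage_seed(cfg.seed, f"pagel-{trait}"),
            trait_name=trait,
        )
        out[trait] = {
            "sweep": sweep,
            "bins": pagel_sweep.summarize_sweep(
                sweep,
                n_bins=min(cfg.n_bins, sweep.thresholds.size),
                seed=stage_seed(cfg.seed, f"pagel-bins-{trait}"),
            ),
        }
    return out


def _mating_stage(data: AnalysisDataset, cfg: RunConfig) -> dict:
    learn = data.labels("learning_binary")
    out = {}
    for column in ("mating_system", "epp_class"):
        trait = data.labels(column)
        try:
            out[column] = pagel_sweep.run_pagel_binary(
                data.tree,
                learn,
                trait,
                runs=cfg.runs_binary,
                seed=stage_seed(cfg.seed, f"mating-{column}"),
            )
        except ValueError as exc:
            out[column] = {"inapplicable": str(exc)}
    return out


# ----------------------------------------------------------------------
# full run and jackknife
# ----------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured stages and (optionally) write a report.

    Returns a dict of stage results; with ``config.outdir`` set, also
    writes Tables-shaped CSVs plus a JSON manifest carrying the seed and
    config hash.  A failing stage is recorded as an error entry without
    discarding completed stages.
    """
    cfg = config.resolved()
    data = load_dataset(cfg)
    results: dict[str, object] = {"config_hash": cfg.content_hash(), "seed": cfg.seed}
    stages = {
        "asr": lambda: _asr_stage(data, cfg),
        "phylanova": lambda: {
            "binary": _phylanova_stage(data, cfg, "learning_binary"),
            "ternary": _phylanova_stage(data, cfg, "learning_ternary"),
        },
        "pgls": lambda: _pgls_stage(data, cfg),
        "brownie": lambda: _brownie_stage(data, cfg),
        "pagel": lambda: _pagel_stage(data, cfg),
        "mating": lambda: _mating_stage(data, cfg),
    }
    for name in cfg.analyses:
        if name not in stages:
            raise ValueError(f"unknown analysis stage {name!r}")
        try:
            results[name] = stages[name]()
        except Exception as exc:  # stage isolation
            results[name] = {"error": f"{type(exc).__name__}: {exc}"}
    results["skipped_species"] = data.skipped_species
    if cfg.outdir:
        _write_report(results, data, cfg)
    return results


def _write_report(results: dict, data: AnalysisDataset, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": results["config_hash"],
        "aggregation": cfg.aggregation,
        "n_species": int(len(data.table)),
        "stages": [k for k in results if k not in ("config_hash", "seed")],
    }
    if "phylanova" in results and isinstance(results["phylanova"], dict):
        for key, df in results["phylanova"].items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"phylanova_{key}.csv", index=False)
                ph = df.attrs.get("posthoc")
                if ph is not None and len(ph):
                    ph.to_csv(out / f"phylanova_{key}_posthoc.csv", index=False)
    if "pgls" in results and isinstance(results["pgls"], pd.DataFrame):
        results["pgls"].to_csv(out / "pgls.csv", index=False)
    if "brownie" in results and isinstance(results["brownie"], dict):
        for key, df in results["brownie"].items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"brownie_{key}.csv", index=False)
    if "asr" in results and isinstance(results["asr"], dict) and "ll_er" in results["asr"]:
        asr = {
            k: v for k, v in results["asr"].items() if not k.startswith("_")
        }
        (out / "asr.json").write_text(json.dumps(asr, indent=2) + "\n")
    if "pagel" in results and isinstance(results["pagel"], dict):
        for trait, res in results["pagel"].items():
            if "sweep" not in res:
                continue
            rows = [
                {
                    "threshold": r["threshold"],
                    "run": r["run"],
                    "ll_independent": r["ll_independent"],
                    "ll_dependent": r["ll_dependent"],
                    "p": r["p_value"],
                    **{
                        name: rate
                        for name, rate in zip(
                            pagel_sweep.DEP_RATE_NAMES, r["dependent_rates"]
                        )
                    },
                }
                for r in res["sweep"].runs
            ]
            pd.DataFrame(rows).to_csv(out / f"pagel_sweep_{trait}.csv", index=False)
            bin_rows = []
            for b in res["bins"]:
                row = {
                    "bin": b["bin"],
                    "percent_significant": b["percent_significant"],
                    "n_runs": b["n_runs"],
                }
                row.update({f"mean_{k}": v for k, v in b["mean_rates"].items()})
                bin_rows.append(row)
            pd.DataFrame(bin_rows).to_csv(out / f"pagel_bins_{trait}.csv", index=False)
    if "mating" in results and isinstance(results["mating"], dict):
        summary = {}
        for column, res in results["mating"].items():
            if "inapplicable" in res:
                summary[column] = res
            else:
                summary[column] = {
                    "percent_significant": res["percent_significant"],
                    "mean_p": res["mean_p"],
                    "mean_rates": res["mean_rates"],
                    "n_runs": res["n_runs"],
                }
        (out / "mating.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def jackknife(
    config: RunConfig,
    unit: str = "family",
    scope: Sequence[str] = ("phylanova",),
    min_family_size: int = 4,
    family_filter: str | None = None,
) -> pd.DataFrame:
    """Leave-one-unit-out re-analysis.

    ``unit='family'`` drops each family represented by at least
    ``min_family_size`` species in turn; ``unit='species'`` drops each
    species of ``family_filter`` in turn.  Each re-run repeats the
    scoped stages on the reduced dataset (sweep runs reduced to 20) and
    the summary flags results whose significance status flips relative
    to the full run.  Re-runs that empty a comparison group are marked
    inapplicable rather than failing.
    """
    import dataclasses

    cfg = config.resolved()
    full = run_full_analysis(
        dataclasses.replace(cfg, analyses=tuple(scope), outdir=None)
    )
    data = load_dataset(cfg)
    fam = data.table["family"]
    if unit == "family":
        counts = fam.value_counts()
        units = [
            ("family", f, set(data.table.index[fam == f]))
            for f in counts[counts >= min_family_size].index
        ]
    elif unit == "species":
        if family_filter is None:
            raise ValueError("species jackknife needs family_filter")
        units = [
            ("species", s, {s})
            for s in data.table.index[fam == family_filter]
        ]
    else:
        raise ValueError("unit must be 'family' or 'species'")

    rows = []
    for kind, name, drop in units:
        keep = set(data.table.index) - drop
        sub_cfg = dataclasses.replace(
            cfg, analyses=tuple(scope), outdir=None,
            runs_per_threshold=min(cfg.runs_per_threshold, 20),
        )
        try:
            sub_data_rows = data.table.loc[sorted(keep)]
            sub = run_full_analysis_on_subset(sub_cfg, data, keep)
        except ValueError as exc:
            rows.append(
                {"unit": kind, "left_out": name, "status": "inapplicable",
                 "detail": str(exc)}
            )
            continue
        flips = _significance_flips(full, sub)
        rows.append(
            {
                "unit": kind,
                "left_out": name,
                "status": "ok",
                "n_species": len(sub_data_rows),
                "n_flips": len(flips),
                "flips": "; ".join(flips),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis_on_subset(
    cfg: RunConfig, data: AnalysisDataset, keep: Iterable[str]
) -> dict:
    """Re-run the configured stages on a species subset of a dataset."""
    keep = set(keep)
    binary = {s: v for s, v in data.labels("learning_binary").items() if s in keep}
    if len(set(binary.values())) < 2:
        raise ValueError("leave-out empties a learning-state group")
    sub_tree = prune_to_taxa(data.tree, keep)
    sub = AnalysisDataset(
        table=data.table.loc[sorted(keep)],
        tree=sub_tree,
        aggregation=data.aggregation,
    )
    results: dict[str, object] = {"config_hash": cfg.content_hash(), "seed": cfg.seed}
    stages = {
        "asr": lambda: _asr_stage(sub, cfg),
        "phylanova": lambda: {
            "binary": _phylanova_stage(sub, cfg, "learning_binary"),
        },
        "pgls": lambda: _pgls_stage(sub, cfg),
        "brownie": lambda: _brownie_stage(sub, cfg),
        "pagel": lambda: _pagel_stage(sub, cfg),
        "mating": lambda: _mating_stage(sub, cfg),
    }
    for name in cfg.analyses:
        results[name] = stages[name]()
    return results


def _significance_flips(full: dict, sub: dict, alpha: float = 0.05) -> list[str]:
    flips = []
    for stage in ("phylanova", "brownie"):
        if stage not in full or stage not in sub:
            continue
        f_res, s_res = full[stage], sub[stage]
        if not isinstance(f_res, dict) or not isinstance(s_res, dict):
            continue
        for key in f_res:
            if key not in s_res:
                continue
            fd, sd = f_res[key], s_res[key]
            if not isinstance(fd, pd.DataFrame) or not isinstance(sd, pd.DataFrame):
                continue
            fmap = dict(zip(fd["trait"], fd["p"] < alpha))
            smap = dict(zip(sd["trait"], sd["p"] < alpha))
            for trait, sig in fmap.items():
                if trait in smap and smap[trait] != sig:
                    flips.append(f"{stage}/{key}/{trait}")
    return flips
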