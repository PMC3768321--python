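"""One-call orchestration: distances -> ordination -> morphospace ->
disparity -> rates -> statistics, with a manifest of seeds and parameters.

The configuration is a plain dictionary (typically loaded from YAML by
the CLI).  Inputs are either file paths (``matrix``, ``tree`` or
``topology`` + ``ranges`` + ``calibration``, ``groups``) or a
``synthetic`` block passed to the generator.  Every stochastic step
derives its seed from the single top-level ``seed``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from morphorates import __version__
from morphorates.disparity import (
    bin_taxa,
    group_profiles,
    profiles_to_frame,
)
from morphorates.distances import ged_matrix, patristic_distances
from morphorates.io_core import (
    DEFAULT_RATE_BINS,
    DEFAULT_TIME_BINS,
    TimeBins,
    read_character_matrix,
    read_ranges,
    read_tree,
)
from morphorates.morphospace import ancestral_coordinates, k_with_envelope
from morphorates.ordination import pcoa
from morphorates.rates import (
    BranchChangeSet,
    branch_rates,
    completeness_correct,
    fitch_optimize,
    rate_equality_tests,
    rate_time_regression,
    rates_by_interval,
    rates_newick,
)
from morphorates.stats import (
    anosim,
    diversity_disparity_correlation,
    kruskal_wallis,
    mantel,
    npmanova,
    pairwise_mann_whitney,
)
from morphorates.timescale import calibrate_tree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def branch_groups(
    changes: BranchChangeSet, tip_groups: dict[str, str], residue: str = "basal"
) -> dict[str, str]:
    """Assign each branch to a group by its descendant tips.

    Branches whose descendant tips all share one group get that group;
    branches subtending a mixture (tree backbone) go to ``residue`` —
    appropriate when the residue is a basal paraphyletic array.
    """
    out = {}
    for edge in changes.tree.branches():
        node = edge.head_node
        tips = {l.taxon.label for l in node.leaf_iter()}
        gs = {tip_groups[t] for t in tips if t in tip_groups}
        bid = changes.branch_ids[id(node)]
        out[bid] = gs.pop() if len(gs) == 1 else residue
    return out


def _load_inputs(config: dict):
    if "synthetic" in config:
        from morphorates.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(**config["synthetic"])
        study = simulate_study(cfg)
        return study.matrix, study.tree, study.ranges, study.groups
    matrix = read_character_matrix(
        config["matrix"], dialect=config.get("dialect", "nexus")
    )
    ranges = read_ranges(config["ranges"]) if "ranges" in config else None
    if "tree" in config:
        tree = read_tree(config["tree"], matrix=matrix)
        if ranges and tree.root_age is not None:
            # Newick stores durations only: re-anchor in absolute time so
            # tip ages line up with the first-appearance dates
            fad = {r.taxon: r.fad for r in ranges}
            ages = tree.node_ages()
            offsets = [
                fad[l.taxon.label] - ages[l]
                for l in tree.tree.leaf_node_iter()
                if l.taxon.label in fad
            ]
            if offsets:
                tree.root_age += float(np.median(offsets))
    elif "topology" in config:
        if ranges is None:
            raise PipelineError("timescale", "topology given without ranges")
        topo = read_tree(config["topology"], matrix=matrix)
        tree = calibrate_tree(
            topo,
            ranges,
            method=config.get("calibration", "mbl"),
            mbl=config.get("mbl", 1.0),
            root_buffer=config.get("root_buffer", 2.0),
        )
    else:
        raise PipelineError("inputs", "config needs 'tree' or 'topology'")
    groups = config.get("groups")
    if isinstance(groups, str):
        groups = dict(pd.read_csv(groups).set_index("taxon")["group"])
    return matrix, tree, ranges, groups


def run_pipeline(config: dict, outdir: "str | Path") -> dict:
    """Run the full analysis; write artifacts and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    nperm_mantel = int(config.get("nperm_mantel", 999))
    nperm_group = int(config.get("nperm_group", 9999))
    n_boot = int(config.get("n_bootstrap", 1000))
    nsim_envelope = int(config.get("nsim_envelope", 999))
    n_axes = int(config.get("n_axes", 20))
    optimizations = config.get("optimizations", ["acctran", "deltran"])
    bins = (
        TimeBins(config["bins"]) if "bins" in config else DEFAULT_TIME_BINS
    )
    rate_bins = (
        TimeBins(config["rate_bins"]) if "rate_bins" in config else DEFAULT_RATE_BINS
    )
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "nperm_mantel": nperm_mantel,
            "nperm_group": nperm_group,
            "n_bootstrap": n_boot,
            "nsim_envelope": nsim_envelope,
            "n_axes": n_axes,
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage("inputs")
        matrix, tree, ranges, groups = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc

    # --- distances ---------------------------------------------------------
    try:
        stage("distances")
        ged = ged_matrix(matrix)
        ged.to_csv(outdir / "ged_distances.csv")
        patr = patristic_distances(tree, transform="sqrt")
        patr.to_csv(outdir / "patristic_sqrt_distances.csv")
    except Exception as exc:
        raise PipelineError("distances", str(exc)) from exc

    # --- ordination --------------------------------------------------------
    try:
        stage("ordination")
        n_axes_eff = min(n_axes, ged.n - 1)
        ordn = pcoa(ged, n_axes=n_axes_eff)
        ordn.to_csv(outdir / "pcoa_scores.csv", outdir / "pcoa_eigenvalues.csv")
    except Exception as exc:
        raise PipelineError("ordination", str(exc)) from exc

    # --- morphospace -------------------------------------------------------
    try:
        stage("morphospace")
        anc = ancestral_coordinates(tree, ordn, axes=[0, 1, 2])
        anc.to_csv(outdir / "phylomorphospace_nodes.csv")
        kres = k_with_envelope(
            ordn.scores[:, :3], nsim=nsim_envelope, seed=seed + 10
        )
        kres.to_frame().to_csv(outdir / "ripley_k.csv", index=False)
        frac_above = float(np.mean(kres.clustered_at()[1:]))
    except Exception as exc:
        raise PipelineError("morphospace", str(exc)) from exc

    # --- disparity ---------------------------------------------------------
    try:
        stage("disparity")
        profiles = []
        if groups:
            by_group = {
                g: ordn.scores_for([l for l in ordn.labels if groups.get(l) == g])
                for g in sorted(set(groups.values()))
            }
            for rarefy in (False, True):
                profiles += group_profiles(
                    by_group, n_reps=n_boot, rarefy=rarefy, seed=seed + 20
                )
        bin_members: dict = {}
        if ranges:
            bin_members = bin_taxa(
                [r for r in ranges if r.taxon in ordn.labels], bins
            )
            by_bin = {
                label: ordn.scores_for(taxa)
                for label, taxa in bin_members.items()
                if len(taxa) >= 2
            }
            if by_bin:
                for rarefy in (False, True):
                    profiles += group_profiles(
                        by_bin, n_reps=n_boot, rarefy=rarefy, seed=seed + 21
                    )
        disparity_table = profiles_to_frame(profiles)
        disparity_table.to_csv(outdir / "disparity_profiles.csv", index=False)
    except Exception as exc:
        raise PipelineError("disparity", str(exc)) from exc

    # --- rates -------------------------------------------------------------
    rate_results: dict = {}
    try:
        stage("rates")
        for opt in optimizations:
            cs = fitch_optimize(tree, matrix, opt)
            cs = completeness_correct(cs, matrix)
            cs = branch_rates(cs)
            cs.table.to_csv(outdir / f"branch_rates_{opt}.csv")
            (outdir / f"rates_{opt}.nwk").write_text(rates_newick(cs))
            lrt = rate_equality_tests(cs, alpha=config.get("alpha", 0.05))
            lrt.per_branch.to_csv(outdir / f"rate_tests_{opt}.csv")
            by_interval = rates_by_interval(cs, rate_bins)
            try:
                regression = rate_time_regression(by_interval, rate_bins)
            except ValueError as exc:
                logger.warning("rate-time regression skipped: %s", exc)
                regression = None
            rate_results[opt] = {
                "changes": cs,
                "lrt": lrt,
                "by_interval": by_interval,
                "regression": regression,
            }
    except Exception as exc:
        raise PipelineError("rates", str(exc)) from exc

    # --- statistics --------------------------------------------------------
    try:
        stage("stats")
        summary: dict = {"clustering_fraction_above_envelope": frac_above}
        patr_sub = patr.subset(ged.labels)
        for coef in ("spearman", "kendall", "pearson"):
            res = mantel(ged, patr_sub, coef=coef, nperm=nperm_mantel, seed=seed + 30)
            summary[f"mantel_{coef}"] = {"statistic": res.statistic, "p": res.p}
        if groups:
            for g in sorted(set(groups.values())):
                drop = {l for l, gg in groups.items() if gg == g}
                if ged.n - len(drop) >= 4:
                    res = mantel(
                        ged.drop(drop),
                        patr_sub.drop(drop),
                        coef="spearman",
                        nperm=nperm_mantel,
                        seed=seed + 31,
                    )
                    summary[f"mantel_spearman_excl_{g}"] = {
                        "statistic": res.statistic,
                        "p": res.p,
                    }
            glabels = np.array([groups[l] for l in ordn.labels])
            np_res = npmanova(
                ordn.scores, glabels, nperm=nperm_group, seed=seed + 32
            )
            an_res = anosim(ged, glabels, nperm=nperm_group, seed=seed + 33)
            summary["npmanova"] = {"F": np_res.statistic, "p": np_res.p}
            summary["anosim"] = {"R": an_res.statistic, "p": an_res.p}
            if np_res.extra is not None:
                np_res.extra.to_csv(outdir / "npmanova_pairwise.csv", index=False)
            for opt, rr in rate_results.items():
                cs = rr["changes"]
                bg = branch_groups(cs, groups)
                incl = cs.included()
                samples = {}
                for g in sorted(set(bg.values())):
                    ids = [b for b in incl.index if bg[b] == g]
                    vals = incl.loc[ids, "log10_rate"].to_numpy()
                    if len(vals) >= 2:
                        samples[g] = vals
                if len(samples) >= 2:
                    h, p = kruskal_wallis(list(samples.values()))
                    summary[f"kruskal_{opt}"] = {"H": h, "p": p}
                    pairwise_mann_whitney(samples).to_csv(
                        outdir / f"mann_whitney_{opt}.csv", index=False
                    )
                summary[f"rate_regression_{opt}"] = rr["regression"]
                summary[f"rate_lrt_{opt}"] = {
                    "statistic": rr["lrt"].global_statistic,
                    "df": rr["lrt"].global_df,
                    "p": rr["lrt"].global_p,
                    "n_high": int((rr["lrt"].per_branch["flag"] == "high").sum()),
                    "n_low": int((rr["lrt"].per_branch["flag"] == "low").sum()),
                }
        if ranges and bin_members:
            mids = DEFAULT_TIME_BINS.midpoints if bins is DEFAULT_TIME_BINS else bins.midpoints
            labels = bins.labels
            usable = [
                lab for lab in labels if len(bin_members.get(lab, [])) >= 2
            ]
            if len(usable) >= 4:
                counts = np.array([len(bin_members[lab]) for lab in usable])
                mid_map = dict(zip(labels, mids))
                times = np.array([mid_map[lab] for lab in usable])
                unrare = disparity_table[
                    (disparity_table["group"].isin(usable))
                    & (~disparity_table["rarefied"])
                    & (disparity_table["index"] == "sum_ranges")
                ].set_index("group")["mean"]
                disp = unrare.loc[usable].to_numpy()
                for differenced in (False, True):
                    r, p = diversity_disparity_correlation(
                        disp, counts, times, differenced=differenced
                    )
                    key = "diversity_disparity_" + (
                        "differenced" if differenced else "raw"
                    )
                    summary[key] = {"r": r, "p": p}
        manifest["summary"] = summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
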