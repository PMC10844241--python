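"""End-to-end pipeline orchestration from a YAML config.

Stages run in dependency order on synthetic inputs generated from the
config: panel simulation -> per-tissue distances, expression trees and
relative-rate tests -> per-gene model selection and change events ->
tissue-overlap / coincidental-index summaries and tau specificity -> atlas
simulation, markers and homology scores -> count sampling and sex-bias
calls.  A JSON manifest records the seed, parameters, wall times, row
counts and input checksums.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from exprevo import distance, homology, models, patterns, sexbias, specificity
from exprevo.io import write_table
from exprevo.simulate import (
    SexEffectSpec,
    SimSpec,
    panel_to_counts,
    simulate_atlas_pair,
    simulate_panel,
)
from exprevo.tree import OUParams, drosophila_tree

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "exprevo_run",
    "n_genes": 400,
    "n_replicates": 3,
    "tissues": ["antenna", "proboscis", "foreleg", "ovipositor", "larva"],
    "sexed_tissues": ["antenna", "proboscis", "foreleg"],
    "coincidental_fraction": 0.1,
    "sex_effect_fraction": 0.05,
    "sex_fold_change": 4.0,
    "model_tissue": "antenna",
    "outgroup": "Dsuz",
    "rate_test_genes": 200,
    "rate_test_reps": 100,
    "n_bootstrap": 100,
    "max_shifts": 3,
    "atlas_clusters": 6,
    "atlas_shared": 3,
    "atlas_genes": 300,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key: {key}")
        config[key] = value
    return config


def run_pipeline(config: dict) -> Path:
    """Run all stages; returns the run directory."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "config": config, "stages": {}}
    tree = drosophila_tree()
    meta = {"seed": seed}

    def stage(name):
        t0 = time.time()

        def done(rows):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 2),
                "rows": int(rows),
            }
            logger.info("stage %-12s %6.2fs rows=%d", name, time.time() - t0, rows)

        return done

    # --- simulate ---------------------------------------------------------
    done = stage("simulate")
    spec = SimSpec(
        tree=tree,
        n_genes=int(config["n_genes"]),
        n_replicates=int(config["n_replicates"]),
        tissues=list(config["tissues"]),
        sexed_tissues=tuple(config["sexed_tissues"]),
        coincidental_fraction=float(config["coincidental_fraction"]),
        sex_effect=SexEffectSpec(
            float(config["sex_effect_fraction"]), float(config["sex_fold_change"])
        ),
        seed=seed,
    )
    panel, truth = simulate_panel(spec)
    panel.write_tsv(outdir / "panel")
    write_table(truth["events"], outdir / "truth_events.tsv", meta, index=False)
    done(panel.values.shape[0])

    # --- distances / trees / rates ---------------------------------------
    done = stage("disttree")
    outgroup = config["outgroup"]
    rows = 0
    trees = {}
    for tissue in spec.tissues:
        means = panel.species_means(tissue=tissue)
        D = distance.sou_distance(means)
        write_table(D, outdir / f"dist_{tissue}.tsv", meta)
        etree = distance.nj_tree_with_support(
            means, outgroup, n_bootstrap=int(config["n_bootstrap"]), seed=seed
        )
        (outdir / f"tree_{tissue}.nwk").write_text(etree.newick() + "\n")
        trees[tissue] = etree
        rows += len(D)
    done(rows)

    done = stage("relrate")
    tissue = config["model_tissue"]
    means = panel.species_means(tissue=tissue)
    ingroup = [s for s in means.columns if s != outgroup]
    pairs = [(a, b) for i, a in enumerate(ingroup) for b in ingroup[i + 1 :]]
    results = distance.subsampled_rate_test(
        means,
        pairs,
        outgroup,
        n_genes=int(config["rate_test_genes"]),
        n_reps=int(config["rate_test_reps"]),
        seed=seed,
    )
    write_table(
        distance.rate_test_table(results), outdir / "rate_tests.tsv", meta, index=False
    )
    done(len(results))

    # --- gene models / events ---------------------------------------------
    done = stage("genemodels")
    all_events = []
    fits_by_tissue = {}
    for tis in spec.tissues:
        sub = panel.subset(tissue=tis)
        Y = np.log2(sub.values + 1.0)
        fits = models.select_models(
            Y, list(sub.meta["species"]), tree, max_shifts=int(config["max_shifts"])
        )
        fits_by_tissue[tis] = fits
        all_events.append(models.change_events(fits, tree, tis))
    fits = fits_by_tissue[config["model_tissue"]]
    fit_rows = [
        {
            "gene": f.gene,
            "selected": f.selected,
            "pbic": f.best.pbic if not f.degenerate else np.nan,
            "alpha": f.best.alpha if not f.degenerate else np.nan,
            "sigma2": f.best.sigma2 if not f.degenerate else np.nan,
            "n_shifts": f.best.n_shifts if not f.degenerate else 0,
        }
        for f in fits
    ]
    write_table(pd.DataFrame(fit_rows), outdir / "gene_fits.tsv", meta, index=False)
    events = pd.concat(all_events, ignore_index=True)
    write_table(events, outdir / "events.tsv", meta, index=False)
    classes = models.classify_branches(fits, tree)
    write_table(classes, outdir / "branch_classes.tsv", meta, index_label="edge")
    done(len(events))

    # --- coincidence / overlap / tau ---------------------------------------
    done = stage("coincidence")
    overlap = patterns.tissue_overlap(events, spec.tissues)
    write_table(overlap.to_frame("genes"), outdir / "tissue_overlap.tsv", meta)
    ci = patterns.coincidental_index_table(events, len(spec.tissues))
    write_table(ci.to_frame(), outdir / "coincidental_index.tsv", meta)
    assoc = patterns.coincidence_vs_branch_length(events, tree, n_permutations=2000, seed=seed)
    (outdir / "coincidence_vs_length.json").write_text(json.dumps(assoc, indent=1))
    done(len(ci))

    done = stage("tau")
    by_tissue = pd.DataFrame(
        {tis: panel.species_means(tissue=tis).mean(axis=1) for tis in spec.tissues}
    )
    taus = specificity.tau_table(by_tissue)
    write_table(taus.to_frame(), outdir / "tau_tissue.tsv", meta)
    done(len(taus))

    # --- atlas / homology ---------------------------------------------------
    done = stage("homology")
    atlas_a, atlas_b, truth_map = simulate_atlas_pair(
        n_clusters=int(config["atlas_clusters"]),
        n_genes=int(config["atlas_genes"]),
        n_shared_clusters=int(config["atlas_shared"]),
        seed=seed,
    )
    markers_a = homology.find_markers(atlas_a)
    markers_b = homology.find_markers(atlas_b)
    score = homology.homology_score(
        atlas_a.summarize(), atlas_b.summarize(), markers_a, markers_b
    )
    write_table(score, outdir / "homology_score.tsv", meta)
    done(score.size)

    # --- counts / sex bias --------------------------------------------------
    done = stage("sexbias")
    counts = panel_to_counts(panel, seed=seed)
    # per-species sex-bias analysis on the sexed tissues (one species in the demo)
    sub = counts.values.loc[
        :, counts.meta["tissue"].isin(config["sexed_tissues"])
    ]
    sub_meta = counts.meta.loc[sub.columns]
    res = sexbias.nb_wald(sub.loc[:, sub_meta["species"] == tree.tip_names[0]],
                          sub_meta[sub_meta["species"] == tree.tip_names[0]])
    cls = sexbias.classify_bias(res)
    write_table(cls, outdir / "sex_bias.tsv", meta, index=False)
    done(len(cls))

    manifest["inputs"] = {
        "panel": str(outdir / "panel.expr.tsv"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir
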