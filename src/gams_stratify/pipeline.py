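"""End-to-end orchestration: simulate -> qc -> cluster -> markers ->
assoc -> keywords -> comm.

Every stage reads the previous stage's persisted plain-text outputs
(MTX/CSV/JSON) from the run directory and writes its own, so stages are
independently runnable and the whole run is reproducible: re-running
with the same configuration and seed yields identical checksums for all
deterministic outputs.  Stage seeds derive from the global seed by fixed
offsets.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, qc, synthdata
from . import commscore, focal_assoc, markers, nlp_keywords, normalize_cluster

STAGES = ("simulate", "qc", "cluster", "markers", "assoc", "keywords", "comm")
_STAGE_SEED_OFFSET = {name: 101 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass
class RunConfig:
    seed: int = 7
    synth: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)
    keywords: dict = field(default_factory=dict)
    comm: dict = field(default_factory=dict)
    skip: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def demo(cls) -> "RunConfig":
        return cls.from_yaml(os.path.join(os.path.dirname(__file__), "demo.yaml"))

    def effective(self) -> dict:
        """Full parameter echo with defaults resolved."""
        out = asdict(self)
        out["synth"] = asdict(_synth_config(self))
        out["synth"]["populations"] = [asdict(p) for p in _synth_config(self).populations]
        out["qc"] = asdict(qc.QCThresholds(**self.qc))
        out["cluster"] = {**_CLUSTER_DEFAULTS, **self.cluster}
        out["markers"] = {**_MARKER_DEFAULTS, **self.markers}
        out["assoc"] = {**_ASSOC_DEFAULTS, **self.assoc}
        out["keywords"] = {**_KEYWORD_DEFAULTS, **self.keywords}
        out["comm"] = {**_COMM_DEFAULTS, **self.comm}
        return out


_CLUSTER_DEFAULTS = dict(theta=100.0, n_hvg=3000, n_pcs=30, k_neighbors=20,
                         resolution=1.0, n_zscore_genes=50)
_MARKER_DEFAULTS = dict(min_pct=0.5, logfc_min=0.25, anchor=None)
_ASSOC_DEFAULTS = dict(
    focal="SORL1", bins="auto", alpha=0.05, n_trees=300, subset_size=None,
    n_perm=25, perm_trees=100, train_fraction=0.75, n_top_heatmap=25,
)
_KEYWORD_DEFAULTS = dict(vocab_size=2000, words_per_doc=40, min_df=2, top_k=10,
                         markers_per_cluster=20, corpus=None)
_COMM_DEFAULTS = dict(n_perm=100, Kh=0.5, hill_n=1.0, n_decoys=8,
                      split_group=None, bin_edges=list(commscore.FOCAL_BIN_EDGES),
                      groups=None)


def _synth_config(cfg: RunConfig) -> synthdata.SynthConfig:
    raw = dict(cfg.synth)
    pops = raw.pop("populations", None)
    kwargs = dict(raw)
    if pops is not None:
        kwargs["populations"] = [synthdata.PopulationSpec(**p) for p in pops]
    kwargs.setdefault("seed", cfg.seed + _STAGE_SEED_OFFSET["simulate"])
    return synthdata.SynthConfig(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner over a persistent run directory."""

    def __init__(self, config: RunConfig, outdir: str):
        self.cfg = config
        self.outdir = os.fspath(outdir)
        os.makedirs(self.outdir, exist_ok=True)
        self.timings: dict[str, float] = {}

    # -- helpers ---------------------------------------------------------
    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)

    def _stage_seed(self, stage: str) -> int:
        return self.cfg.seed + _STAGE_SEED_OFFSET[stage]

    def _filtered(self):
        return io.read_10x(self.path("filtered"))

    def _truth(self):
        return synthdata.GroundTruth.from_json(self.path("ground_truth.json"))

    def _residuals(self, adata):
        p = {**_CLUSTER_DEFAULTS, **self.cfg.cluster}
        return normalize_cluster.pearson_residuals(adata, theta=p["theta"])

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        scfg = _synth_config(self.cfg)
        adata, truth = synthdata.generate_dataset(scfg)
        io.write_10x(adata, self.path("raw"))
        truth.to_json(self.path("ground_truth.json"))

    def stage_qc(self) -> None:
        adata = io.read_10x(self.path("raw"))
        thr = qc.QCThresholds(**self.cfg.qc)
        metrics = qc.compute_qc_metrics(adata)
        filtered, report = qc.filter_cells_genes(adata, thr, metrics)
        io.write_10x(filtered, self.path("filtered"))
        with open(self.path("filter_report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

    def stage_cluster(self) -> None:
        p = {**_CLUSTER_DEFAULTS, **self.cfg.cluster}
        adata = self._filtered()
        norm = self._residuals(adata)
        hvg = normalize_cluster.select_hvg(norm, n_top=min(p["n_hvg"], adata.n_vars))
        sub = norm.subset_genes(hvg)
        emb = normalize_cluster.pca_embed(sub, n_pcs=p["n_pcs"])
        clustering = normalize_cluster.cluster_cells(
            emb, k_neighbors=p["k_neighbors"], resolution=p["resolution"],
            seed=self._stage_seed("cluster"),
        )
        pd.DataFrame(
            emb.coords, index=adata.obs_names,
            columns=[f"PC{i+1}" for i in range(emb.coords.shape[1])],
        ).to_csv(self.path("embedding.csv"))
        pd.DataFrame(
            {"cluster": clustering.labels}, index=adata.obs_names
        ).to_csv(self.path("clusters.csv"))
        pd.Series(hvg, name="gene").to_csv(self.path("hvg.csv"), index=False)
        z, order = normalize_cluster.cluster_mean_zscores(
            norm, clustering, hvg[: p["n_zscore_genes"]]
        )
        z.iloc[order].to_csv(self.path("zscores.csv"))

    def stage_markers(self) -> None:
        p = {**_MARKER_DEFAULTS, **self.cfg.markers}
        adata = self._filtered()
        labels = self._labels(adata)
        expr = normalize_cluster.log_normalize(adata)
        table = markers.find_markers(
            expr, labels, min_pct=p["min_pct"], logfc_min=p["logfc_min"]
        )
        table.to_csv(self.path("markers.csv"), index=False)

        focal = {**_ASSOC_DEFAULTS, **self.cfg.assoc}["focal"]
        rows = []
        if focal in expr.columns:
            vals = np.expm1(expr[focal].to_numpy())
            for cl in np.unique(labels):
                rows.append({"cluster": int(cl),
                             "FC": markers.cluster_fold_change(vals, labels, cl)})
        pd.DataFrame(rows).to_csv(self.path("focal_cluster_fc.csv"), index=False)
        anchor = p["anchor"]
        summary = {}
        if anchor and anchor in adata.var_names and focal in adata.var_names:
            summary["coexpression_pct"] = markers.coexpression_fraction(adata, focal, anchor)
        with open(self.path("markers_summary.json"), "w") as fh:
            json.dump(summary, fh)

    def _labels(self, adata) -> np.ndarray:
        cl = pd.read_csv(self.path("clusters.csv"), index_col=0)
        return cl.loc[adata.obs_names, "cluster"].to_numpy()

    def stage_assoc(self) -> None:
        p = {**_ASSOC_DEFAULTS, **self.cfg.assoc}
        adata = self._filtered()
        expr = normalize_cluster.log_normalize(adata)
        norm = self._residuals(adata)
        focal = p["focal"]
        if focal not in expr.columns:
            raise KeyError(f"focal gene {focal!r} missing after QC")

        screen = focal_assoc.spearman_screen(
            expr.drop(columns=[]), focal, alpha=p["alpha"]
        )
        screen.to_csv(self.path("spearman.csv"), index=False)

        fvals = norm.to_frame()[focal].to_numpy()
        if p["bins"] == "auto":
            cuts = focal_assoc.quantile_cutpoints(fvals)
        elif p["bins"] == "paper":
            cuts = focal_assoc.SORL1_CUTPOINTS
        else:
            cuts = tuple(float(x) for x in p["bins"])
        disc = focal_assoc.discretize_expression(fvals, cuts)

        X = expr.drop(columns=[focal])
        st = focal_assoc.MCFSSettings(
            n_trees=p["n_trees"], subset_size=p["subset_size"]
        )
        perm_st = focal_assoc.MCFSSettings(
            n_trees=p["perm_trees"], subset_size=p["subset_size"]
        )
        seed = self._stage_seed("assoc")
        ranking = focal_assoc.mcfs_significance(
            X, disc, settings=st, n_perm=p["n_perm"], perm_settings=perm_st,
            alpha=p["alpha"], seed=seed,
        )
        out = ranking.table.copy()
        out["cutoff"] = ranking.cutoff
        out.sort_values("rank").to_csv(self.path("ri_ranking.csv"))

        sig = ranking.significant_genes()
        validation = {"n_significant": len(sig), "cut_points": list(disc.cut_points),
                      "bin_counts": disc.counts()}
        if sig:
            report = focal_assoc.validate_classifiers(
                X[sig], disc, train_fraction=p["train_fraction"], seed=seed
            )
            validation["report"] = report.to_dict()
        with open(self.path("validation.json"), "w") as fh:
            json.dump(validation, fh, indent=2)

        top = out.sort_values("rank").index[: p["n_top_heatmap"]]
        labels = self._labels(adata)
        clustering = normalize_cluster.Clustering(
            labels=labels, n_clusters=int(labels.max()) + 1,
            resolution=0.0, seed=0, cells=adata.obs_names,
        )
        z, order = normalize_cluster.cluster_mean_zscores(norm, clustering, list(top))
        z.iloc[order].to_csv(self.path("zscores_top_ri.csv"))

    def stage_keywords(self) -> None:
        p = {**_KEYWORD_DEFAULTS, **self.cfg.keywords}
        if p["corpus"]:
            corpus = synthdata.GeneDocCorpus.from_tsv(p["corpus"])
        else:
            truth = self._truth()
            corpus = synthdata.generate_gene_docs(
                truth, vocab_size=p["vocab_size"], words_per_doc=p["words_per_doc"],
                seed=self._stage_seed("keywords"),
            )
        tfidf = nlp_keywords.build_tfidf(corpus, min_df=p["min_df"])
        mk = pd.read_csv(self.path("markers.csv"))
        gene_sets = {
            f"cluster{cl}": list(
                sub.sort_values("fdr")["gene"].head(p["markers_per_cluster"])
            )
            for cl, sub in mk.groupby("cluster")
        }
        gene_sets = {k: v for k, v in gene_sets.items() if v}
        table = nlp_keywords.keywords_for_gene_sets(tfidf, gene_sets, top_k=p["top_k"])
        table.to_csv(self.path("keywords.csv"), index=False)

    def stage_comm(self) -> None:
        p = {**_COMM_DEFAULTS, **self.cfg.comm}
        adata = self._filtered()
        truth = self._truth()
        expr = np.expm1(normalize_cluster.log_normalize(adata))
        labels = self._labels(adata)

        if p["groups"]:
            cluster_to_group = {int(k): v for k, v in p["groups"].items()}
            base = pd.Series(
                [cluster_to_group.get(int(c), "other") for c in labels],
                index=adata.obs_names,
            )
        else:
            # synthetic stand-in for the expert annotation step: map each
            # cluster to the majority planted population
            pops = truth.cell_population.loc[adata.obs_names]
            base = pd.Series(index=adata.obs_names, dtype=object)
            for cl in np.unique(labels):
                mask = labels == cl
                base[mask] = pops[mask].mode().iloc[0]
        focal = {**_ASSOC_DEFAULTS, **self.cfg.assoc}["focal"]
        split = p["split_group"]
        if split:
            fvals = normalize_cluster.log_normalize(adata)[focal]
            groups = commscore.assign_groups(
                base, fvals, split_group=split, bin_edges=tuple(p["bin_edges"])
            )
        else:
            groups = base
        db = synthdata.generate_lr_database(
            truth, n_decoys=p["n_decoys"], seed=self._stage_seed("comm")
        )
        db.to_csv(self.path("lr_database.csv"), index=False)
        tensor = commscore.permutation_pvalues(
            expr, groups, db, n_perm=p["n_perm"], Kh=p["Kh"], n=p["hill_n"],
            seed=self._stage_seed("comm"),
        )
        long = tensor.to_long()
        long.to_csv(self.path("comm_probability.csv"), index=False)
        for direction in ("outgoing", "incoming"):
            commscore.pattern_contributions(tensor, direction).to_csv(
                self.path(f"contributions_{direction}.csv")
            )

    # -- driver ----------------------------------------------------------
    def run(self, only: str | None = None) -> dict:
        stages = [only] if only else [s for s in STAGES if s not in self.cfg.skip]
        for name in stages:
            if name not in STAGES:
                raise ValueError(f"unknown stage {name!r}")
            t0 = time.perf_counter()
            try:
                getattr(self, f"stage_{name}")()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            self.timings[name] = time.perf_counter() - t0
        return self.summary(stages)

    def summary(self, stages) -> dict:
        outputs = {}
        for root, _, files in os.walk(self.outdir):
            for f in sorted(files):
                if f == "summary.json":
                    continue
                p = os.path.join(root, f)
                outputs[os.path.relpath(p, self.outdir)] = _sha256(p)
        summary = {
            "version": __version__,
            "stages_run": list(stages),
            "seed": self.cfg.seed,
            "parameters": self.cfg.effective(),
            "timings_sec": {k: round(v, 3) for k, v in self.timings.items()},
            "checksums": outputs,
        }
        with open(self.path("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        return summary


def run_pipeline(config: RunConfig, outdir: str, stage: str | None = None) -> dict:
    """Run the configured pipeline (or a single stage) into ``outdir``."""
    return Pipeline(config, outdir).run(only=stage)
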