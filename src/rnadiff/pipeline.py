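"""Stage orchestration: overlap → normalize → statistics → summarize.

Each stage reads and writes plain-text files in the output directory, so
a run can be executed end-to-end or stage by stage (rerunning the
statistics stage with a different family on cached counts, say). All
outputs are deterministic functions of the manifest parameters: reruns
are byte-identical regardless of thread count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from . import de_stats, gene_models, normalize, overlap_counter, summarize

logger = logging.getLogger("rnadiff")

__all__ = ["PipelineConfig", "RunManifest", "STAGES", "run_pipeline", "run_stage"]

_FLOAT_FMT = "%.10g"


class ConfigurationError(ValueError):
    """Bad or missing configuration / inputs (CLI exit code 2)."""


class StageError(RuntimeError):
    """A stage failed mid-run (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All parameters of a run; fully determines every output."""

    annotation: str = ""
    sample_sheet: str = ""  # TSV: file, sample, label
    out: str = "rnadiff_out"
    gene_model: str = "ui"  # ui | union
    anchor: str = "3prime"  # 3prime | 5prime:K
    family: str = "poisson"
    norm_mode: str = "offset"
    norm_method: str = "quantile"
    quantile: float = 0.75
    outcome: str = "factor"
    permutations: int = 0
    top: int = 50
    seed: int = 2010
    pseudocount: float = 0.5
    threads: int = 1

    def model_mode(self) -> str:
        return {"ui": "union_intersection", "union": "union"}.get(self.gene_model, self.gene_model)

    def model_spec(self) -> de_stats.ModelSpec:
        return de_stats.ModelSpec(
            family=self.family,
            norm_mode=self.norm_mode,
            outcome=self.outcome,
            pseudocount=self.pseudocount,
        )

    def path(self, name: str) -> str:
        return os.path.join(self.out, name)


@dataclass
class RunManifest:
    """Flat key-value record of parameters and per-stage counts."""

    values: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "RunManifest":
        vals = {f"param.{k}": str(v) for k, v in asdict(config).items()}
        vals["version"] = __version__
        return cls(vals)

    def set(self, key: str, value) -> None:
        self.values[key] = str(value)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.values):
                fh.write(f"{k}={self.values[k]}\n")

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        vals = {}
        with open(path) as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.rstrip("\n").split("=", 1)
                    vals[k] = v
        return cls(vals)

    def to_config(self) -> PipelineConfig:
        cfg = PipelineConfig()
        for f_name, f_val in asdict(cfg).items():
            key = f"param.{f_name}"
            if key in self.values:
                setattr(cfg, f_name, type(f_val)(self.values[key]))
        return cfg


def _read_sample_sheet(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ConfigurationError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("file", "sample", "label"):
        if col not in df.columns:
            raise ConfigurationError(f"sample sheet lacks required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# stages


def _stage_model(config: PipelineConfig, manifest: RunManifest) -> None:
    genes = gene_models.parse_annotation(config.annotation)
    models = gene_models.build_all_gene_models(genes, mode=config.model_mode())
    gene_models.export_bed(models, config.path("intervals.bed"))
    gene_models.export_gene_table(models, config.path("genes.tsv"))
    manifest.set("stage.model.genes", len(models))
    manifest.set("stage.model.nonempty_genes", sum(1 for m in models if m.length))


def _stage_overlap(config: PipelineConfig, manifest: RunManifest) -> None:
    _require(config.path("intervals.bed"), "model")
    models = gene_models.import_bed(config.path("intervals.bed"))
    sheet = _read_sample_sheet(config.sample_sheet)
    policy = overlap_counter.AnchorPolicy.parse(config.anchor)
    samples = list(sheet["sample"])
    labels = dict(zip(sheet["sample"], sheet["label"]))

    def stream():
        skip: dict[str, int] = {}
        n_read = 0
        for path in dict.fromkeys(sheet["file"]):  # unique, order-preserving
            rows = sheet[sheet["file"] == path]
            one_sample = rows["sample"].iloc[0] if len(rows) == 1 else None
            for aln in overlap_counter.read_alignments(path, sample=one_sample, skip_tally=skip):
                n_read += 1
                yield aln
        manifest.set("stage.overlap.reads_seen", n_read)
        manifest.set("stage.overlap.reads_skipped_unmapped", skip.get("unmapped", 0))

    cm, records = overlap_counter.count_overlaps(
        stream(), models, policy, samples=samples, labels=labels
    )
    cm.to_tsv(config.path("counts.tsv"))
    overlap_counter.write_overlap_records(records, config.path("overlaps.tsv"))
    manifest.set("stage.overlap.reads_assigned", len(records))


def _stage_normalize(config: PipelineConfig, manifest: RunManifest) -> None:
    _require(config.path("counts.tsv"), "overlap")
    cm = overlap_counter.CountMatrix.from_tsv(config.path("counts.tsv"))
    filtered = normalize.filter_expressed_genes(cm)
    filtered.to_tsv(config.path("counts_filtered.tsv"))
    factors = normalize.normalization_factors(
        filtered, method=config.norm_method, p=config.quantile
    )
    factors.to_tsv(config.path("factors.tsv"))
    manifest.set("stage.normalize.genes_filtered", cm.m - filtered.m)
    manifest.set("stage.normalize.genes_tested", filtered.m)


def _stage_statistics(config: PipelineConfig, manifest: RunManifest) -> None:
    _require(config.path("counts_filtered.tsv"), "normalize")
    _require(config.path("factors.tsv"), "normalize")
    sheet = _read_sample_sheet(config.sample_sheet)
    labels_map = dict(zip(sheet["sample"], sheet["label"]))
    cm = overlap_counter.CountMatrix.from_tsv(config.path("counts_filtered.tsv"), labels=labels_map)
    factors = normalize.NormalizationFactors.from_tsv(config.path("factors.tsv"))
    if factors.samples != cm.samples:
        raise StageError("factors and counts disagree on samples")
    spec = config.model_spec()
    labels = cm.label_vector()
    if spec.outcome == "continuous":
        labels = [float(v) for v in labels]
    designs = de_stats.design_matrix(labels, factors, spec)

    D, p, conv = _lrt_threaded(cm.counts, designs, spec, config.threads)
    p_perm = np.full(cm.m, np.nan)
    if config.permutations > 0:
        nulls = de_stats.permute_null(
            cm, labels, factors, spec, B=config.permutations, seed=config.seed
        )
        p_perm = de_stats.permutation_pvalues(D, nulls)
        null_df = pd.DataFrame(
            nulls.matrix, index=cm.genes,
            columns=[f"perm{b + 1}" for b in range(nulls.B)],
        )
        null_df.index.name = "gene_id"
        null_df.to_csv(config.path("null_stats.tsv"), sep="\t", float_format=_FLOAT_FMT)
    out = pd.DataFrame(
        {
            "gene_id": cm.genes,
            "D": D,
            "df": designs.df,
            "p_asymptotic": p,
            "p_permutation": p_perm,
            "converged": conv,
        }
    )
    out.to_csv(config.path("stats.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest.set("stage.statistics.genes_tested", cm.m)
    manifest.set("stage.statistics.nonconverged", int((~conv).sum()))


def _lrt_threaded(counts: np.ndarray, designs, spec, threads: int):
    """Per-gene tests are independent; chunk genes across workers and
    concatenate in gene order (bitwise identical for any worker count)."""
    m = counts.shape[0]
    threads = max(1, threads)
    if threads == 1 or m < 2 * threads:
        return de_stats.lrt_all(counts, designs, spec)
    bounds = np.linspace(0, m, threads + 1, dtype=int)
    chunks = [(counts[a:b]) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    with ThreadPoolExecutor(max_workers=threads) as pool:
        parts = list(pool.map(lambda c: de_stats.lrt_all(c, designs, spec), chunks))
    return tuple(np.concatenate([p[i] for p in parts]) for i in range(3))


def _stage_summarize(config: PipelineConfig, manifest: RunManifest) -> None:
    _require(config.path("stats.tsv"), "statistics")
    stats_df = pd.read_csv(config.path("stats.tsv"), sep="\t")
    use_perm = config.permutations > 0 and stats_df["p_permutation"].notna().all()
    pcol = "p_permutation" if use_perm else "p_asymptotic"
    results = [
        de_stats.TestResult(
            gene_id=str(r.gene_id),
            D=float(r.D),
            df=int(r.df),
            p_asymptotic=float(getattr(r, pcol)),
            p_permutation=float(r.p_permutation) if use_perm else None,
            converged=bool(r.converged),
        )
        for r in stats_df.itertuples(index=False)
    ]
    q = summarize.qvalues(stats_df[pcol].to_numpy())
    table = summarize.results_table(results, q)

    ranked = table.sort_values([pcol.replace("p_permutation", "p_asymptotic"), "gene_id"])
    ranked[["gene_id", "p_asymptotic"]].rename(columns={"p_asymptotic": "p"}).to_csv(
        config.path("pvalues.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    table.sort_values(["q", "gene_id"])[["gene_id", "q"]].to_csv(
        config.path("qvalues.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    summarize.pvalue_histogram(stats_df[pcol]).to_csv(
        config.path("pvalue_histogram.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )

    cm = overlap_counter.CountMatrix.from_tsv(config.path("counts_filtered.tsv"))
    models = gene_models.import_bed(config.path("intervals.bed"))
    rpkm = summarize.rpkm_table(cm, models)
    rpkm.to_csv(config.path("rpkm.tsv"), sep="\t", float_format=_FLOAT_FMT)

    top = summarize.top_genes(results, config.top)
    pd.DataFrame({"gene_id": [r.gene_id for r in top], "p": [r.p_asymptotic for r in top]}).to_csv(
        config.path("top_genes.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if os.path.exists(config.path("overlaps.tsv")):
        ov = pd.read_csv(config.path("overlaps.tsv"), sep="\t")
        keep = {r.gene_id for r in top}
        ov[ov["gene_id"].isin(keep)].to_csv(
            config.path("top_overlaps.tsv"), sep="\t", index=False
        )
    manifest.set("stage.summarize.top_genes", len(top))


def _require(path: str, producing_stage: str) -> None:
    if not os.path.exists(path):
        raise ConfigurationError(
            f"missing input {path}; run the {producing_stage!r} stage first"
        )


STAGES: dict[str, object] = {
    "model": _stage_model,
    "overlap": _stage_overlap,
    "normalize": _stage_normalize,
    "statistics": _stage_statistics,
    "summarize": _stage_summarize,
}


def run_stage(stage_name: str, config: PipelineConfig, manifest: RunManifest | None = None) -> RunManifest:
    """Run one named stage; inputs must already exist. Returns the
    updated manifest (also written to out/manifest.txt)."""
    if stage_name not in STAGES:
        raise ConfigurationError(
            f"unknown stage {stage_name!r}; valid stages: {', '.join(STAGES)}"
        )
    os.makedirs(config.out, exist_ok=True)
    mpath = config.path("manifest.txt")
    if manifest is None:
        manifest = RunManifest.load(mpath) if os.path.exists(mpath) else RunManifest.from_config(config)
        manifest.values.update(RunManifest.from_config(config).values)
    try:
        STAGES[stage_name](config, manifest)
        manifest.set(f"stage.{stage_name}.status", "ok")
    except ConfigurationError:
        raise
    except Exception as exc:
        manifest.set(f"stage.{stage_name}.status", f"failed: {exc}")
        manifest.save(mpath)
        raise StageError(f"stage {stage_name!r} failed: {exc}") from exc
    manifest.save(mpath)
    return manifest


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages in order; returns the output directory.

    Inputs are validated before any stage runs; on a stage failure the
    partial outputs are retained with the manifest marking the failure.
    """
    if not os.path.exists(config.annotation):
        raise ConfigurationError(f"annotation not found: {config.annotation}")
    sheet = _read_sample_sheet(config.sample_sheet)
    for f in sheet["file"]:
        if not os.path.exists(f):
            raise ConfigurationError(f"alignment file not found: {f}")
    os.makedirs(config.out, exist_ok=True)
    manifest = RunManifest.from_config(config)
    for name in STAGES:
        logger.info("running stage %s", name)
        manifest = run_stage(name, config, manifest)
    return config.out
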