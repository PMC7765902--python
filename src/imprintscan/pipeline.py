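"""Pipeline orchestration, run manifests, and the grain-weight utility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .asr import build_ledger, read_asr_tsv, write_asr_tsv
from .caller import CHI2_CRITICAL, DEFAULT_MIN_TOTAL_ASR, call_all_genes, summarize_calls
from .clusters import (
    clustered_fraction,
    excess_test,
    find_mini_clusters,
    neighbor_null,
    write_clusters_tsv,
)
from .conservation import (
    RICE_BACKGROUND_N,
    bhr_match,
    conservation_verdict,
    overlap_counts,
    overlap_null,
    read_score_tsv,
    write_bhr_tsv,
)
from .design import read_design_tsv
from .genome import read_bed
from .pseudogenome import read_vcf


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Single source of thresholds and paths for a run.

    Threshold defaults are the analysis constants: FPKM 0.5, chi-square
    critical 3.84 (exact df=1 alpha=0.05 quantile), MEG folds 4 (endosperm)
    / 2 (embryo), PEG folds 1 / 2, BHR 0.95, min total ASR 10 per cross,
    10,000 permutation replicates, 37,852-gene background.
    """

    paths: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    fpkm_threshold: float = 0.5
    chi2_critical: float = CHI2_CRITICAL
    meg_fold_endosperm: float = 4.0
    meg_fold_embryo: float = 2.0
    peg_fold_endosperm: float = 1.0
    peg_fold_embryo: float = 2.0
    bhr_threshold: float = 0.95
    min_total_asr: int = DEFAULT_MIN_TOTAL_ASR
    reps: int = 10_000
    background_n: int = RICE_BACKGROUND_N
    neighbor_n_select: int | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "fpkm_threshold",
            "chi2_critical",
            "meg_fold_endosperm",
            "meg_fold_embryo",
            "peg_fold_endosperm",
            "peg_fold_embryo",
            "bhr_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")
        if self.simulate is None:
            for key in ("asr", "design", "bed"):
                if key not in self.paths:
                    raise ConfigError(f"config needs paths.{key} (or a simulate section)")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigError(f"paths.{key}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GrainMetrics:
    """Hundred- and thousand-grain weight from a bulk weighing."""

    total_weight: float
    n_grains: int
    hgw: float
    tgw: float


def grain_weight(total_weight: float, n_grains: int) -> GrainMetrics:
    """HGW = (grain weight / number of grains) x 100; TGW x 1000."""
    if n_grains <= 0:
        raise ValueError("n_grains must be positive")
    if total_weight < 0:
        raise ValueError("total_weight must be non-negative")
    per_grain = total_weight / n_grains
    return GrainMetrics(total_weight, n_grains, per_grain * 100.0, per_grain * 1000.0)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every configured stage; returns the manifest dict.

    Deterministic given config + seed. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "imprintscan",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "thresholds": {
            "fpkm": config.fpkm_threshold,
            "chi2_critical": config.chi2_critical,
            "meg_fold": {"endosperm": config.meg_fold_endosperm, "embryo": config.meg_fold_embryo},
            "peg_fold": {"endosperm": config.peg_fold_endosperm, "embryo": config.peg_fold_embryo},
            "bhr": config.bhr_threshold,
            "min_total_asr": config.min_total_asr,
        },
        "stages": {},
    }

    # ---------------------------------------------------------- load inputs
    try:
        if config.simulate is not None:
            from .synthetic import simulate_dataset

            ds = simulate_dataset(seed=config.seed, **config.simulate)
            ds.write(out / "synthetic")
            genome, variants, design, records = ds.genome, ds.variants, ds.design, ds.records
            manifest["stages"]["simulate"] = {
                "genes": genome.n_genes,
                "variants": len(variants),
                "records": len(records),
            }
        else:
            genome = read_bed(config.paths["bed"])
            design = read_design_tsv(config.paths["design"])
            records = read_asr_tsv(config.paths["asr"])
            variants = read_vcf(config.paths["vcf"]) if "vcf" in config.paths else None
            manifest["stages"]["load"] = {"genes": genome.n_genes, "records": len(records)}
    except (OSError, ValueError, KeyError) as e:
        raise StageError("input", str(e)) from e

    # ------------------------------------------------------------- calling
    try:
        meg_fold = {"endosperm": config.meg_fold_endosperm, "embryo": config.meg_fold_embryo}
        peg_fold = {"endosperm": config.peg_fold_endosperm, "embryo": config.peg_fold_embryo}
        calls = call_all_genes(
            records,
            design,
            min_total_asr=config.min_total_asr,
            critical=config.chi2_critical,
            meg_fold=meg_fold,
            peg_fold=peg_fold,
        )
        _write_calls(calls, design, out / "calls.tsv")
        summary = summarize_calls(calls.values())
        manifest["stages"]["call"] = summary
    except (ValueError, KeyError) as e:
        raise StageError("call", str(e)) from e

    # -------------------------------------------------------------- ledger
    try:
        genes_with_snp = (
            variants.genes_with_variants(genome) if variants is not None else set(calls)
        )
        pair_id = design.pair_ids()[0]
        ledger = build_ledger(pair_id, genome.gene_ids_in_order(), genes_with_snp, records, calls)
        ledger.write_tsv(out / "ledger.tsv")
        manifest["stages"]["ledger"] = ledger.counts()
    except (ValueError, KeyError) as e:
        raise StageError("ledger", str(e)) from e

    # ------------------------------------------------------------ clusters
    try:
        imprinted = {g: c.klass for g, c in calls.items() if c.is_imprinted}
        mini = find_mini_clusters(imprinted, genome)
        write_clusters_tsv(mini, out / "clusters.tsv")
        stage: dict[str, Any] = {"n_clusters": len(mini)}
        if imprinted:
            frac = clustered_fraction(mini, len(imprinted))
            n_sel = config.neighbor_n_select or len(imprinted)
            null = neighbor_null(genome, n_sel, reps=config.reps, seed=config.seed)
            null.write_json(out / "neighbor_null.json")
            stage.update(excess_test(frac, null))
        manifest["stages"]["clusters"] = stage
    except (ValueError, KeyError) as e:
        raise StageError("clusters", str(e)) from e

    # ------------------------------------------------------- set overlaps
    if "sets" in config.paths or any(k.startswith("set_") for k in config.paths):
        try:
            set_paths = {
                k.removeprefix("set_"): v for k, v in config.paths.items() if k.startswith("set_")
            }
            sets = {lab: Path(p).read_text().split() for lab, p in set_paths.items()}
            observed = overlap_counts(sets)
            report: dict[str, Any] = {"observed": observed, "background_n": config.background_n}
            labels = list(sets)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    null = overlap_null(
                        [len(set(sets[labels[i]])), len(set(sets[labels[j]]))],
                        config.background_n,
                        reps=config.reps,
                        seed=config.seed,
                    )
                    key = f"{labels[i]}&{labels[j]}"
                    report[key] = conservation_verdict(observed[key], null)
            if len(labels) == 3:
                null = overlap_null(
                    [len(set(sets[lab])) for lab in labels],
                    config.background_n,
                    reps=config.reps,
                    seed=config.seed,
                    statistic="k_way",
                )
                key = "&".join(labels)
                report[key] = conservation_verdict(observed[key], null)
            (out / "overlap.json").write_text(json.dumps(report, indent=2) + "\n")
            manifest["stages"]["overlap"] = {k: v for k, v in report.items() if k != "observed"}
        except (OSError, ValueError) as e:
            raise StageError("overlap", str(e)) from e

    # ----------------------------------------------------------------- BHR
    if "bhr_forward" in config.paths and "bhr_reverse" in config.paths:
        try:
            pairs = bhr_match(
                read_score_tsv(config.paths["bhr_forward"]),
                read_score_tsv(config.paths["bhr_reverse"]),
                threshold=config.bhr_threshold,
            )
            write_bhr_tsv(pairs, out / "bhr_pairs.tsv")
            manifest["stages"]["bhr"] = {"n_pairs": len(pairs)}
        except (OSError, ValueError) as e:
            raise StageError("bhr", str(e)) from e
    else:
        manifest["stages"]["bhr"] = {"skipped": "no cross-species score tables configured"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_calls(calls, design, path: Path) -> None:
    cross_ids = design.cross_ids()
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tclass\ttissue_evidence\t"
            + "\t".join(f"chi2_{c}" for c in cross_ids)
            + "\t"
            + "\t".join(f"fold_mp_{c}" for c in cross_ids)
            + "\n"
        )
        for g, call in calls.items():
            tissue = call.tissue_evidence
            pick = tissue if tissue in ("endosperm", "embryo") else "endosperm"
            chi2s, folds = [], []
            for c in cross_ids:
                st = call.stats.get(c, {}).get(pick)
                chi2s.append(f"{st.chi2:.4g}" if st else "NA")
                folds.append(f"{st.fold_mp:.4g}" if st else "NA")
            fh.write(
                f"{g}\t{call.klass}\t{tissue or 'NA'}\t" + "\t".join(chi2s) + "\t" + "\t".join(folds) + "\n"
            )
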