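"""Configuration and one-command pipeline runner.

Chains the analysis stages — simulation (optional), genome loading,
windowed divergence (+ NJ tree), D statistics, f-hat, per-block ML
topologies, and the admixture map — writing every stage's outputs plus a
manifest into one output directory.  All randomness derives from the master
seed; each stage gets an independent stream keyed by the stage name, so a
stage rerun in isolation reproduces its in-pipeline result.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genomes import (
    PseudoHaploidGenome,
    read_chrom_table,
    read_fasta,
    shared_frame,
    write_chrom_table,
    write_fasta,
)
from .windows import partition_windows
from .sim import AdmixtureEvent, SimConfig, simulate, write_truth
from .pseudohap import iter_pileup, sample_pseudohaploid, sample_from_vcf
from .divergence import distance_matrix, kde_density, neighbor_joining, window_divergence
from .dstat import d_test, f_hat
from .blocktree import best_topologies
from .admixmap import (
    build_admixture_map,
    excess_admixture_fraction,
    map_to_bed,
    run_lengths,
    topology_fractions,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "load", "divergence", "dstat", "fhat", "blocktrees", "admixmap")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration (JSON round-trips exactly)."""

    outdir: str
    seed: int = 0
    window_size: int = 1_000_000
    mode: str = "tv"  # tv | all
    gap_threshold: float = 0.5
    min_baseq: int = 30
    min_mapq: int = 30
    jackknife_weighted: bool = True
    chrom_table: str | None = None
    fasta: dict[str, str] = field(default_factory=dict)  # sample -> FASTA path
    pileup: dict[str, str] = field(default_factory=dict)  # sample -> pileup TSV path
    vcf: str | None = None
    historical: list[str] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)  # role -> sample label
    autosomes: list[str] | None = None
    simulate: dict | None = None  # SimConfig kwargs; replaces input paths

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def sample_names(self) -> list[str]:
        if self.simulate is not None:
            return list(self.simulate.get("populations", ("P1", "P2", "P3", "O")))
        names = list(self.fasta) or list(self.pileup)
        return names

    def validate(self) -> None:
        required = {"p1", "p2", "outgroup"}
        if not required <= set(self.roles):
            raise ValueError(f"roles must define at least {sorted(required)}")
        if "p3" not in self.roles and "p3a" not in self.roles:
            raise ValueError("roles must define p3 (or p3a/p3b)")
        known = set(self.sample_names())
        if self.vcf is None and known:
            undefined = {r: s for r, s in self.roles.items() if s not in known}
            if undefined:
                raise ValueError(f"roles reference undeclared samples: {undefined}")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one named stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def read_alignment_set(
    paths: dict[str, str], chrom_lengths: dict[str, int] | None = None,
    historical: list[str] = (),
) -> dict[str, PseudoHaploidGenome]:
    """Load per-sample FASTAs and validate a shared coordinate frame."""
    genomes = {
        name: read_fasta(p, name=name, historical=name in historical)
        for name, p in paths.items()
    }
    frame = shared_frame(list(genomes.values()))
    if chrom_lengths is not None:
        for chrom, L in chrom_lengths.items():
            if frame.get(chrom) != L:
                raise ValueError(
                    f"chromosome {chrom!r}: FASTA length {frame.get(chrom)} != table {L}"
                )
    return genomes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the manifest dict.

    Outputs are deterministic given the config (including seed): a rerun
    produces byte-identical files.  On stage failure, partial outputs are
    retained next to a FAILED marker naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.json")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    current = "setup"

    def record(stage: str, outputs: list[str], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s done (%.2fs)", stage, time.time() - t0)

    try:
        # ---- inputs ------------------------------------------------------
        genomes: dict[str, PseudoHaploidGenome]
        if config.simulate is not None:
            current = "simulate"
            t0 = time.time()
            kwargs = dict(config.simulate)
            kwargs.setdefault("seed", config.seed)
            kwargs.setdefault("window_size", config.window_size)
            kwargs["chrom_lengths"] = {
                str(c): int(L) for c, L in kwargs["chrom_lengths"].items()
            }
            if "admixture_events" in kwargs:
                kwargs["admixture_events"] = tuple(
                    AdmixtureEvent(**e) if isinstance(e, dict) else AdmixtureEvent(*e)
                    for e in kwargs["admixture_events"]
                )
            if "populations" in kwargs:
                kwargs["populations"] = tuple(kwargs["populations"])
            if "historical" in kwargs:
                kwargs["historical"] = tuple(kwargs["historical"])
            sim_config = SimConfig(**kwargs)
            genomes, truth = simulate(sim_config)
            outs = []
            for name, g in genomes.items():
                p = outdir / f"{name}.fa"
                write_fasta(g, p)
                outs.append(p.name)
            write_truth(truth, outdir / "truth_tracts.tsv", outdir / "truth_classes.tsv")
            write_chrom_table(sim_config.chrom_lengths, outdir / "chroms.tsv")
            (outdir / "sim_config.json").write_text(sim_config.to_json())
            outs += ["truth_tracts.tsv", "truth_classes.tsv", "chroms.tsv", "sim_config.json"]
            chrom_lengths = sim_config.chrom_lengths
            record("simulate", outs, t0)
        else:
            current = "load"
            t0 = time.time()
            chrom_lengths = (
                read_chrom_table(config.chrom_table) if config.chrom_table else None
            )
            if config.fasta:
                genomes = read_alignment_set(config.fasta, chrom_lengths, config.historical)
            elif config.pileup:
                if chrom_lengths is None:
                    raise ValueError("pileup input requires a chromosome table")
                genomes = {
                    name: sample_pseudohaploid(
                        iter_pileup(path),
                        chrom_lengths,
                        min_baseq=config.min_baseq,
                        min_mapq=config.min_mapq,
                        seed=config.seed,
                        name=name,
                        historical=name in config.historical,
                    )
                    for name, path in config.pileup.items()
                }
            elif config.vcf:
                if chrom_lengths is None:
                    raise ValueError("VCF input requires a chromosome table")
                genomes = sample_from_vcf(
                    config.vcf,
                    chrom_lengths,
                    seed=config.seed,
                    historical={h: True for h in config.historical},
                )
            else:
                raise ValueError("no input: set simulate, fasta, pileup or vcf")
            if chrom_lengths is None:
                chrom_lengths = shared_frame(list(genomes.values()))
            record("load", [], t0)

        undefined = {r: s for r, s in config.roles.items() if s not in genomes}
        if undefined:
            raise ValueError(f"roles reference missing samples: {undefined}")
        windows = partition_windows(chrom_lengths, config.window_size)
        r = config.roles
        p1, p2, og = genomes[r["p1"]], genomes[r["p2"]], genomes[r["outgroup"]]
        p3 = genomes[r.get("p3", r.get("p3a"))]
        p3b = genomes[r["p3b"]] if "p3b" in r else None

        # ---- divergence --------------------------------------------------
        current = "divergence"
        t0 = time.time()
        ordered = list(genomes.values())
        tables = []
        for ga, gb in combinations(ordered, 2):
            tables.append(window_divergence(ga, gb, windows, mode=config.mode))
        div = pd.concat(tables, ignore_index=True)
        div.to_csv(outdir / "divergence_windows.tsv", sep="\t", index=False,
                   float_format="%.10g")
        curves = []
        for pair, sub in div.groupby("pair", sort=False):
            vals = sub.loc[~sub["excluded"], "divergence"].dropna().to_numpy()
            if vals.size >= 2:
                grid, dens = kde_density(vals)
                curves.append(pd.DataFrame({"pair": pair, "x": grid, "density": dens}))
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(
                outdir / "divergence_density.tsv", sep="\t", index=False,
                float_format="%.10g")
        labels, mat = distance_matrix(ordered, windows, mode=config.mode)
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            outdir / "distance_matrix.tsv", sep="\t", float_format="%.10g")
        (outdir / "nj_tree.nwk").write_text(neighbor_joining(mat, labels) + "\n")
        record("divergence", ["divergence_windows.tsv", "divergence_density.tsv",
                              "distance_matrix.tsv", "nj_tree.nwk"], t0)

        # ---- D statistic -------------------------------------------------
        current = "dstat"
        t0 = time.time()
        res = d_test(p1, p2, p3, og, windows, mode=config.mode,
                     chroms=config.autosomes, weighted=config.jackknife_weighted)
        dtab = pd.DataFrame([{
            "P1": res.roles[0], "P2": res.roles[1], "P3": res.roles[2],
            "O": res.roles[3], "mode": res.mode, "nABBA": res.n_abba,
            "nBABA": res.n_baba, "D": res.d, "SE": res.se, "Z": res.z,
            "M": res.m, "significant": res.significant,
        }])
        dtab.to_csv(outdir / "dstat.tsv", sep="\t", index=False, float_format="%.10g")
        record("dstat", ["dstat.tsv"], t0)

        # ---- f-hat -------------------------------------------------------
        if p3b is not None:
            current = "fhat"
            t0 = time.time()
            fres = f_hat(p1, p2, p3, p3b, og, windows, mode=config.mode,
                         chroms=config.autosomes, weighted=config.jackknife_weighted)
            ftab = pd.DataFrame([{
                "P1": fres.roles[0], "P2": fres.roles[1], "P3a": fres.roles[2],
                "P3b": fres.roles[3], "O": fres.roles[4], "S_num": fres.s_num,
                "S_den": fres.s_den, "fhat": fres.fhat, "SE": fres.se,
                "Z": fres.z, "M": fres.m,
            }])
            ftab.to_csv(outdir / "fhat.tsv", sep="\t", index=False, float_format="%.10g")
            record("fhat", ["fhat.tsv"], t0)

        # ---- block trees -------------------------------------------------
        current = "blocktrees"
        t0 = time.time()
        taxa = [p1, p2, p3, og]
        results = best_topologies(taxa, windows, outgroup=og.name,
                                  gap_threshold=config.gap_threshold)
        rows = []
        for res_w in results:
            rows.append({
                "window": res_w.window,
                "status": res_w.status,
                "best_tree": res_w.rooted_newick or ".",
                "lnL": ";".join(f"{x:.6f}" for x in res_w.log_likelihoods)
                if res_w.log_likelihoods is not None else ".",
                "tie": res_w.tie,
            })
        pd.DataFrame(rows).to_csv(outdir / "blocktrees.tsv", sep="\t", index=False)
        record("blocktrees", ["blocktrees.tsv"], t0)

        # ---- admixture map -----------------------------------------------
        current = "admixmap"
        t0 = time.time()
        labels4 = [g.name for g in taxa]
        focal = r.get("focal", p2.name)
        reference = r.get("reference", p1.name)
        introgressor = r.get("introgressor", p3.name)
        amap = build_admixture_map(results, windows, labels4, focal, reference, introgressor)
        map_to_bed(amap, outdir / "admixture_map.bed")
        fracs = topology_fractions(amap)
        corrected = excess_admixture_fraction(fracs["admix"], fracs["ils_alt"])
        runs_plain = run_lengths(amap, "admix", bridge_missing=False)
        runs_bridged = run_lengths(amap, "admix", bridge_missing=True)
        pd.DataFrame({
            "bridged": [False] * runs_plain.lengths_bp.size
            + [True] * runs_bridged.lengths_bp.size,
            "length_bp": np.concatenate([runs_plain.lengths_bp, runs_bridged.lengths_bp]),
        }).to_csv(outdir / "admix_runs.tsv", sep="\t", index=False)
        summary = {
            "fractions": fracs,
            "corrected_admixture_fraction": corrected,
            "largest_run_bp": runs_plain.largest,
            "largest_run_bridged_bp": runs_bridged.largest,
            "roles": {"focal": focal, "reference": reference,
                      "introgressor": introgressor},
        }
        (outdir / "admixture_summary.json").write_text(json.dumps(summary, indent=2))
        record("admixmap", ["admixture_map.bed", "admix_runs.tsv",
                            "admixture_summary.json"], t0)

    except Exception as exc:  # noqa: BLE001 - stage context is the point
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        manifest["failed_stage"] = current
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(current, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
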