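"""End-to-end orchestration of the locus fine-mapping pipeline.

Stage order: associate -> filter -> LD proxies -> conditional scan ->
annotate -> motif disruption -> cis-eQTL -> prioritize -> 4C profile (when
reads are configured).  Each stage's output is written before the next
begins; a failure aborts with the stage name, leaving any half-written file
with a ``.partial`` suffix.  Every output table carries header lines with
the config hash and seed, so a run is reproducible byte-for-byte from its
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_variants, prioritize, read_bed, read_bedgraph
from .association import associate, conditional_scan, filter_variants
from .eqtl import eqtl_scan, read_expression
from .fourc import (
    CHANNELS,
    assign_reads,
    binned_profile,
    build_fragment_map,
    read_reads_bed,
    smooth_profile,
    write_profile_bedgraph,
)
from .genotypes import read_genotype_table, read_phenotypes
from .ld import ld_proxies
from .motif import allele_delta, load_jaspar

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "PipelineError", "PipelineResult", "load_config", "run_pipeline"]

DEFAULT_CONFIG = {
    "maf_min": 0.01,
    "info_min": 0.80,
    "p_max": 5.0e-7,
    "r2_min": 0.2,
    "fdr": 0.05,
    "motif_delta_min": 3.0,
    "phastcons_min": 0.9,
    "gerp_min": 2.0,
    "fourc_resolution": 100,
    "fourc_window": 5000,
    "min_mapq": 30,
    "exclusion_radius": 1500,
    "eqtl_window_bp": 1_000_000,
    "seed": 0,
    "outdir": "results",
}

_RANGES = {
    "maf_min": (0.0, 0.5),
    "info_min": (0.0, 1.0),
    "p_max": (0.0, 1.0),
    "r2_min": (0.0, 1.0),
    "fdr": (0.0, 1.0),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    report: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)
    config_hash: str = ""
    outputs: dict[str, str] = field(default_factory=dict)


def load_config(path) -> dict:
    """Load a flat JSON config, fill defaults, validate threshold ranges."""
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    merged = {**DEFAULT_CONFIG, **cfg}
    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not (lo <= float(v) <= hi) and not (key == "p_max" and v == float("inf")):
            raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")
    merged["_basedir"] = str(path.parent)
    return merged


def config_hash(config: dict) -> str:
    clean = {k: v for k, v in config.items() if not k.startswith("_")}
    return hashlib.sha256(json.dumps(clean, sort_keys=True).encode()).hexdigest()[:16]


def _resolve(config: dict, key: str) -> Path:
    base = Path(config.get("_basedir", "."))
    value = config[key]
    p = Path(value)
    return p if p.is_absolute() else base / p


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    partial = path.with_name(path.name + ".partial")
    with open(partial, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    os.replace(partial, path)


def run_pipeline(config: dict) -> PipelineResult:
    """Run every configured stage in order and emit the candidate report."""
    chash = config_hash(config)
    header = [f"config_hash={chash}", f"seed={config.get('seed')}", f"finemapkit={__version__}"]
    outdir = _resolve(config, "outdir")
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    outputs: dict[str, str] = {}
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            n_in, n_out = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        rec = {
            "stage": name,
            "n_in": n_in,
            "n_out": n_out,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.append(rec)
        logger.info(json.dumps(rec))

    def _out(name: str) -> Path:
        p = outdir / name
        outputs[name] = str(p)
        return p

    # -- load + associate -------------------------------------------------
    def _associate():
        probs = config.get("probabilities")
        table = read_genotype_table(
            _resolve(config, "genotypes"),
            _resolve(config, "probabilities") if probs else None,
        )
        phen = read_phenotypes(_resolve(config, "phenotypes"))
        order = phen.set_index("sample_id")["status"]
        y = order.loc[table.sample_ids].to_numpy()
        state["table"], state["y"] = table, y
        assoc = associate(table, y, maf_min=config["maf_min"], info_min=config["info_min"])
        state["assoc"] = assoc
        _write_table(assoc, _out("association.tsv"), header)
        return table.n_variants, len(assoc)

    stage("associate", _associate)

    def _filter():
        filtered = filter_variants(
            state["assoc"], config["maf_min"], config["info_min"], config["p_max"]
        )
        state["filtered"] = filtered
        _write_table(filtered, _out("filtered.tsv"), header)
        return len(state["assoc"]), len(filtered)

    stage("filter", _filter)

    def _proxies():
        filtered = state["filtered"]
        if len(filtered) == 0:
            raise ValueError("no variants survive the association filters")
        lead = config.get("lead") or filtered.loc[filtered["p_trend"].idxmin(), "variant_id"]
        state["lead"] = lead
        prox = ld_proxies(state["table"], lead, r2_min=config["r2_min"])
        state["proxies"] = prox
        _write_table(prox, _out("proxies.tsv"), header)
        return len(filtered), len(prox)

    stage("ld_proxies", _proxies)

    def _conditional():
        region = None
        if "region_chrom" in config:
            region = (
                str(config["region_chrom"]),
                int(config["region_start"]),
                int(config["region_end"]),
            )
        cond = conditional_scan(state["table"], state["y"], state["lead"], region)
        state["conditional"] = cond
        _write_table(cond, _out("conditional.tsv"), header)
        return state["table"].n_variants, len(cond)

    stage("conditional_scan", _conditional)

    def _annotate():
        tracks = {
            k[len("track_"):]: read_bed(_resolve(config, k))
            for k in sorted(config)
            if k.startswith("track_")
        }
        cons = {
            k[len("cons_"):]: read_bedgraph(_resolve(config, k))
            for k in sorted(config)
            if k.startswith("cons_")
        }
        ann = annotate_variants(state["filtered"], tracks, cons)
        state["annotations"] = ann
        _write_table(ann, _out("annotations.tsv"), header)
        return len(state["filtered"]), len(ann)

    stage("annotate", _annotate)

    def _motif():
        from pyfaidx import Fasta

        pwm = load_jaspar(_resolve(config, "pfm"))[0]
        fa = Fasta(str(_resolve(config, "genome_fasta")))
        offset = int(config.get("genome_offset", 0))
        radius = pwm.length - 1
        rows = []
        for _, var in state["filtered"].iterrows():
            seq = str(fa[str(var["chrom"])][:])
            local = int(var["pos"]) - 1 - offset
            lo = max(0, local - radius)
            hi = min(len(seq), local + radius + 1)
            ref = state["table"].variants.set_index("variant_id").loc[var["variant_id"]]
            res = allele_delta(seq[lo:hi], local - lo, ref["ref"], ref["alt"], pwm)
            rows.append(
                {
                    "variant_id": var["variant_id"],
                    "best_ref": res.best_ref,
                    "best_alt": res.best_alt,
                    "delta": res.delta,
                }
            )
        mot = pd.DataFrame(rows, columns=["variant_id", "best_ref", "best_alt", "delta"])
        state["motif"] = mot
        _write_table(mot, _out("motif.tsv"), header)
        return len(state["filtered"]), len(mot)

    stage("motif", _motif)

    def _eqtl():
        if "expression" not in config:
            state["eqtl"] = pd.DataFrame(columns=["gene_id", "beta", "se", "p", "n", "q"])
            return 0, 0
        expr = read_expression(_resolve(config, "expression"))
        res = eqtl_scan(
            expr,
            state["table"],
            state["lead"],
            window_bp=int(config["eqtl_window_bp"]),
            exclude_samples=tuple(config.get("eqtl_exclude_samples", ())),
        )
        state["eqtl"] = res
        _write_table(res, _out("eqtl.tsv"), header)
        return len(expr.genes), len(res)

    stage("eqtl", _eqtl)

    def _prioritize():
        deltas = dict(zip(state["motif"]["variant_id"], state["motif"]["delta"]))
        report = prioritize(
            state["filtered"],
            state["annotations"],
            deltas,
            phastcons_min=config["phastcons_min"],
            gerp_min=config["gerp_min"],
            motif_delta_min=config["motif_delta_min"],
        )
        cond = state["conditional"][["variant_id", "p"]].rename(columns={"p": "conditional_p"})
        report = report.merge(cond, on="variant_id", how="left")
        prox = state["proxies"][["variant_id", "r2"]].rename(columns={"r2": "r2_lead"})
        report = report.merge(prox, on="variant_id", how="left")
        report.loc[report["variant_id"] == state["lead"], "r2_lead"] = 1.0
        eq = state["eqtl"]
        sig = eq[eq["q"] < config["fdr"]] if len(eq) else eq
        report["eqtl_gene"] = ""
        report["eqtl_q"] = np.nan
        if len(sig):
            best = sig.loc[sig["q"].idxmin()]
            is_lead = report["variant_id"] == state["lead"]
            report.loc[is_lead, "eqtl_gene"] = best["gene_id"]
            report.loc[is_lead, "eqtl_q"] = best["q"]
        state["report"] = report
        _write_table(report, _out("candidate_report.tsv"), header)
        with open(outdir / "candidate_report.json", "w") as fh:
            json.dump(
                {
                    "config_hash": chash,
                    "seed": config.get("seed"),
                    "version": __version__,
                    "lead": state["lead"],
                    "candidates": json.loads(report.to_json(orient="records")),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        outputs["candidate_report.json"] = str(outdir / "candidate_report.json")
        return len(state["filtered"]), len(report)

    stage("prioritize", _prioritize)

    if config.get("fourc_reads"):

        def _fourc():
            fmap = build_fragment_map(
                _resolve(config, "genome_fasta"),
                offsets={str(config.get("region_chrom", "")): int(config.get("genome_offset", 0))},
            )
            reads = read_reads_bed(_resolve(config, "fourc_reads"))
            vp = config.get("viewpoint")
            viewpoint = (str(vp[0]), int(vp[1]), int(vp[2])) if vp else None
            masked_cfg = config.get("fourc_masked", [])
            chrom = fmap.chroms[0]
            masked = [(chrom, int(s), int(e)) for s, e in masked_cfg]
            counts, rep = assign_reads(
                reads,
                fmap,
                min_mapq=int(config["min_mapq"]),
                viewpoint=viewpoint,
                exclusion_radius=int(config["exclusion_radius"]),
                masked=masked,
            )
            profile = binned_profile(counts, fmap, resolution=int(config["fourc_resolution"]))
            profile = smooth_profile(
                profile,
                window=int(config["fourc_window"]),
                masked=[(int(s), int(e)) for s, e in masked_cfg],
            )
            hdr = "\n".join(f"# {line}" for line in header)
            for ch in CHANNELS:
                write_profile_bedgraph(profile, ch, _out(f"fourc_{ch}.bedgraph"), header=hdr)
                write_profile_bedgraph(
                    profile, ch, _out(f"fourc_{ch}_smoothed.bedgraph"), smoothed=True, header=hdr
                )
            state["fourc_profile"] = profile
            state["fourc_report"] = rep
            return rep["n_input"], rep["n_assigned"]

        stage("fourc_profile", _fourc)

    return PipelineResult(state["report"], log, chash, outputs)
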