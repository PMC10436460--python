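"""End-to-end orchestration with a config object and a reproducibility
manifest.

The pipeline runs, per condition: binning -> low-coverage masking ->
iterative correction -> distance-decay expectation -> Z-scores, decay curve,
compartments (at the compartment resolution), insulation/TADs, and
significant-interaction calls; then, per ordered condition pair: Z-score
difference maps, compartment switch classification, TAD transition
classification and interaction-set overlaps; and finally, when expression
and peak tracks are configured, the integration joins.  The manifest records
the package version, a config hash, per-stage record counts and the sha256
of every output file; paths inside it are relative to the output directory,
so identical (inputs, config, seed) reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genome_io, matrix_ops, decay_norm, compartments, tads, interactions, integration

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    chrom_sizes: str
    conditions: dict  # name -> {"pairs": path} | {"coo": path}
    outdir: str
    genes: str | None = None  # BED or GFF3 by extension
    expression: str | None = None  # TSV: gene_id + <cond>_rep* columns
    peaks: list = field(default_factory=list)  # {mark, condition, path}
    base_bin_size: int = 10_000
    compartment_bin_size: int = 100_000
    interaction_bin_size: int = 10_000
    min_cis_distance: int = 4_000
    mask_quantile: float = 0.02
    tad_square_span: int = 100_000
    tad_delta_span: int = 40_000
    boundary_min_strength: float = 0.1
    min_tad_size_bins: int = 3
    stable_frac: float = 0.75
    member_frac: float = 0.75
    interaction_min_count: int = 2
    interaction_p_max: float = 0.01
    interaction_q_max: float = 0.01
    deg_fc_min: float = 2.0
    deg_p_max: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name, res in (("compartment", self.compartment_bin_size),
                          ("interaction", self.interaction_bin_size),
                          ("tad square span", self.tad_square_span),
                          ("tad delta span", self.tad_delta_span)):
            if res % self.base_bin_size:
                raise ConfigError(
                    f"{name} resolution {res} is not a multiple of the base "
                    f"bin size {self.base_bin_size}")
        if not (0 <= self.mask_quantile < 0.5):
            raise ConfigError("mask_quantile must be in [0, 0.5)")
        if len(self.conditions) == 0:
            raise ConfigError("at least one condition is required")
        for cname, src in self.conditions.items():
            if not ("pairs" in src or "coo" in src):
                raise ConfigError(f"condition {cname}: need 'pairs' or 'coo'")


def load_config(path) -> RunConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_genes(path, chroms) -> pd.DataFrame:
    fmt = "GFF3" if str(path).endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")) else "BED"
    kw = {"feature_type": "gene"} if fmt == "GFF3" else {}
    return genome_io.read_intervals(path, format=fmt, chroms=chroms, **kw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; return the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts_log: dict = {}
    chroms = genome_io.read_chrom_sizes(cfg.chrom_sizes)
    bins = genome_io.make_bins(chroms, cfg.base_bin_size)
    genes = _read_genes(cfg.genes, chroms) if cfg.genes else None

    def stage(name):
        logger.info("stage: %s", name)

    mats: dict[str, matrix_ops.ContactMatrix] = {}
    profiles, ztracks, comp_tracks, tad_sets, inter_calls = {}, {}, {}, {}, {}
    for cname, src in cfg.conditions.items():
        stage(f"{cname}: bin")
        try:
            if "pairs" in src:
                pairs = matrix_ops.read_pairs(src["pairs"], chroms)
                m = matrix_ops.bin_pairs(pairs, bins,
                                         min_cis_distance=cfg.min_cis_distance,
                                         metadata={"condition": cname})
            else:
                m = matrix_ops.read_coo(src["coo"], bins,
                                        metadata={"condition": cname})
            stage(f"{cname}: mask+balance")
            m = matrix_ops.mask_low_coverage(m, cfg.mask_quantile)
            m = matrix_ops.ice_balance(m)
            mats[cname] = m
            counts_log[f"{cname}.bins_unmasked"] = int(m.mask.sum())

            stage(f"{cname}: expected/zscore")
            prof = decay_norm.expected_profile(m)
            profiles[cname] = prof
            prof.to_frame().to_csv(out / f"{cname}.expected.tsv", sep="\t", index=False)
            decay_norm.decay_curve(m).to_csv(out / f"{cname}.decay.tsv",
                                             sep="\t", index=False)
            ztracks[cname] = decay_norm.zscore_transform(m, prof)

            stage(f"{cname}: compartments")
            factor = cfg.compartment_bin_size // cfg.base_bin_size
            mc = matrix_ops.coarsen(m, factor) if factor > 1 else m
            mc = matrix_ops.mask_low_coverage(mc, cfg.mask_quantile)
            mc = matrix_ops.ice_balance(mc)
            track = compartments.call_compartments(mc, genes=genes,
                                                   condition=cname)
            comp_tracks[cname] = track
            track.to_frame().to_csv(out / f"{cname}.compartments.tsv",
                                    sep="\t", index=False)
            counts_log[f"{cname}.compartment_bins_labeled"] = int(
                (track.label != "NA").sum())

            stage(f"{cname}: tads")
            ins = tads.insulation_score(m, cfg.tad_square_span,
                                        cfg.tad_delta_span)
            ins.to_frame().to_csv(out / f"{cname}.insulation.tsv",
                                  sep="\t", index=False)
            bnds = tads.call_boundaries(ins, cfg.tad_delta_span,
                                        cfg.boundary_min_strength)
            tset = tads.derive_tads(bnds, bins, cfg.min_tad_size_bins,
                                    condition=cname)
            tad_sets[cname] = tset
            genome_io.write_bed(tset.tads, out / f"{cname}.tads.bed")
            pd.DataFrame([asdict_boundary(b) for b in bnds]).to_csv(
                out / f"{cname}.boundaries.tsv", sep="\t", index=False)
            counts_log[f"{cname}.n_tads"] = len(tset)
            counts_log[f"{cname}.n_boundaries"] = len(bnds)

            stage(f"{cname}: interactions")
            cis = interactions.call_significant_cis(
                m, min_count=cfg.interaction_min_count,
                p_max=cfg.interaction_p_max, q_max=cfg.interaction_q_max)
            trans = interactions.call_significant_trans(
                m, min_count=cfg.interaction_min_count,
                p_max=cfg.interaction_p_max, q_max=cfg.interaction_q_max)
            sig = pd.concat([cis[cis["significant"]],
                             trans[trans["significant"]] if len(trans) else trans],
                            ignore_index=True)
            inter_calls[cname] = sig
            sig.to_csv(out / f"{cname}.interactions.tsv", sep="\t", index=False)
            counts_log[f"{cname}.n_significant_cis"] = int(
                (sig["kind"] == "cis").sum()) if len(sig) else 0
            counts_log[f"{cname}.n_significant_trans"] = int(
                (sig["kind"] == "trans").sum()) if len(sig) else 0
        except Exception as err:
            raise RuntimeError(f"pipeline failed in condition {cname}: {err}") from err

    names = list(cfg.conditions)
    switch_tracks = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pair = f"{a}_vs_{b}"
            try:
                diff = decay_norm.differential_map(ztracks[a], ztracks[b])
                _write_z(diff, out / f"{pair}.zdiff.coo.tsv")
                sw = compartments.classify_switches(comp_tracks[a], comp_tracks[b])
                switch_tracks[pair] = sw
                sw.regions.to_csv(out / f"{pair}.switch_regions.tsv",
                                  sep="\t", index=False)
                counts_log[f"{pair}.switching_fraction"] = sw.summary["switching_fraction"]
                events, tcounts = tads.classify_transitions(
                    tad_sets[a], tad_sets[b], cfg.stable_frac, cfg.member_frac)
                pd.DataFrame([
                    {"event_id": k, "type": ev.type,
                     "source_ids": ",".join(map(str, ev.source)),
                     "target_ids": ",".join(map(str, ev.target)),
                     "overlap_bp": ev.overlap_bp}
                    for k, ev in enumerate(events)
                ]).to_csv(out / f"{pair}.transitions.tsv", sep="\t", index=False)
                for k, v in tcounts.items():
                    counts_log[f"{pair}.transitions_{k}"] = v
            except Exception as err:
                raise RuntimeError(f"pipeline failed in pair {pair}: {err}") from err
    if len(names) >= 2:
        venn = interactions.compare_interaction_sets(inter_calls)
        venn.to_csv(out / "interaction_overlap.tsv", sep="\t", index=False)

    if cfg.expression and genes is not None:
        try:
            expr = pd.read_csv(cfg.expression, sep="\t")
            rows = []
            for cname in names:
                cols = [c for c in expr.columns if c.startswith(f"{cname}_")]
                if not cols:
                    continue
                vals = expr[cols].mean(axis=1)
                gene_bin = genome_io.assign_to_bins(
                    genes, comp_tracks[cname].bins, rule="majority")
                lab = comp_tracks[cname].label[gene_bin]
                expr_by_gene = dict(zip(expr["gene_id"], vals))
                va = [expr_by_gene[g] for g, l in zip(genes["name"], lab)
                      if l == "A" and g in expr_by_gene]
                vb = [expr_by_gene[g] for g, l in zip(genes["name"], lab)
                      if l == "B" and g in expr_by_gene]
                if len(va) >= 3 and len(vb) >= 3:
                    res = integration.expression_compare(np.array(va), np.array(vb))
                    res["condition"] = cname
                    rows.append(res)
            pd.DataFrame(rows).to_csv(out / "expression_by_compartment.tsv",
                                      sep="\t", index=False)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    c1 = [c for c in expr.columns if c.startswith(f"{a}_")]
                    c2 = [c for c in expr.columns if c.startswith(f"{b}_")]
                    if not c1 or not c2:
                        continue
                    degs = integration.deg_call_simple(
                        expr, c1, c2, cfg.deg_fc_min, cfg.deg_p_max)
                    degs.to_csv(out / f"{a}_vs_{b}.degs.tsv", sep="\t", index=False)
                    counts_log[f"{a}_vs_{b}.n_up"] = int((degs["status"] == "up").sum())
                    counts_log[f"{a}_vs_{b}.n_down"] = int((degs["status"] == "down").sum())
                    sw = switch_tracks.get(f"{a}_vs_{b}")
                    if sw is not None and len(sw.regions):
                        enr = integration.deg_region_enrichment(
                            degs, sw.regions, genes)
                        enr.to_csv(out / f"{a}_vs_{b}.deg_enrichment.tsv",
                                   sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"pipeline failed in integration: {err}") from err

    if cfg.peaks:
        try:
            psets: dict[tuple[str, str], integration.PeakSet] = {}
            for spec in cfg.peaks:
                iv = genome_io.read_intervals(spec["path"], format="BED",
                                              chroms=chroms)
                psets[(spec["mark"], spec["condition"])] = integration.PeakSet(
                    mark=spec["mark"], condition=spec["condition"], intervals=iv)
            marks = sorted({k[0] for k in psets})
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    sw = switch_tracks.get(f"{a}_vs_{b}")
                    if sw is None:
                        continue
                    gl_rows = []
                    for mark in marks:
                        if (mark, a) in psets and (mark, b) in psets:
                            _, cnts = integration.peak_gain_loss(
                                psets[(mark, a)], psets[(mark, b)], sw)
                            cnts.insert(0, "mark", mark)
                            gl_rows.append(cnts)
                    if gl_rows:
                        pd.concat(gl_rows, ignore_index=True).to_csv(
                            out / f"{a}_vs_{b}.peak_gain_loss.tsv",
                            sep="\t", index=False)
            for (mark, cond), ps in sorted(psets.items()):
                if cond in tad_sets:
                    prof = integration.boundary_peak_profile(ps, tad_sets[cond])
                    prof.to_csv(out / f"{cond}.{mark}.boundary_profile.tsv",
                                sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"pipeline failed in peak integration: {err}") from err

    cfg_dict = asdict(cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": cfg.seed,
        "record_counts": counts_log,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n")
    return manifest


def asdict_boundary(b) -> dict:
    return {"bin_id": b.bin_id, "chrom": b.chrom, "position": b.position,
            "strength": b.strength}


def _write_z(z, path) -> None:
    import scipy.sparse as sp
    coo = sp.triu(z.valid).tocoo()
    zvals = np.asarray(z.z[coo.row, coo.col]).ravel()
    order = np.lexsort((coo.col, coo.row))
    pd.DataFrame({"bin_i": coo.row[order], "bin_j": coo.col[order],
                  "z": zvals[order], "valid": 1}).to_csv(
        path, sep="\t", index=False)
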