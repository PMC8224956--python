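"""End-to-end orchestration: simulate -> filter -> assoc -> hommap -> LD.

One seeded :class:`RunConfig` drives the whole analysis; every stage
threshold defaults to the mapping study's value (allele balance 0.4-0.6,
DP/GQ >= 30, 5 kb scaffolds, MAF >= 5%, >= 10 homozygotes per class,
hom-pool AF > 0.85, wt-pool AF < 0.15, 10 kb windows, >= 5 variants,
alpha = 0.01).  The run writes all intermediates as plain VCF/TSV/BED
plus a consolidated JSON report that is byte-identical when re-run with
the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .assoc import (association_scan, compute_kinship, effective_tests,
                    fit_null_variance_components, fwer_threshold)
from .filters import (FilterConfig, filter_association_markers,
                      filter_founder_het, mask_low_quality_calls)
from .hommap import ConcordanceRule, rank_candidates, window_scan
from .simulate import ColonyConfig, ColonyData, simulate_colony
from .synteny import ld_decay, ld_matrix, project_markers

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_colony"]


@dataclass
class RunConfig:
    seed: int = 1
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    rule: ConcordanceRule = field(default_factory=ConcordanceRule)
    alpha: float = 0.01
    window_size: int = 10_000
    min_variants: int = 5
    top_k: int = 10
    ld_markers: int = 30
    ld_permutations: int = 2000

    def __post_init__(self) -> None:
        # one run seed fans out deterministically: colony gets child 0,
        # the LD permutation stream child 1
        self.colony.seed = int(
            np.random.SeedSequence(self.seed).spawn(1)[0].generate_state(1)[0]
            % (2 ** 31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("colony"), dict):
            d["colony"] = ColonyConfig.from_dict(d["colony"])
        for key, sub in (("filters", FilterConfig), ("rule", ConcordanceRule)):
            if isinstance(d.get(key), dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    report: dict
    data: ColonyData
    association: pd.DataFrame
    windows: pd.DataFrame
    ranked_windows: pd.DataFrame
    ordered_markers: pd.DataFrame
    ld_r2: np.ndarray
    filter_report: pd.DataFrame


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def causal_window_rank(ranked: pd.DataFrame, scaffold: str, pos: int,
                       window_size: int) -> int | None:
    """1-based rank of the window containing the causal position among all
    qualifying windows, or None if that window does not qualify."""
    k = (pos - 1) // window_size
    hit = (ranked["scaffold"] == scaffold) & (ranked["start"] == k * window_size)
    idx = np.flatnonzero(hit.to_numpy())
    return int(idx[0]) + 1 if len(idx) else None


def analyze_colony(data: ColonyData, cfg: RunConfig) -> PipelineResult:
    """Run every analysis stage on an in-memory colony."""
    scaffold_lengths = dict(zip(data.scaffold_lengths["scaffold"],
                                data.scaffold_lengths["length"]))
    report: dict = {"seed": cfg.seed, "config": cfg.to_dict()}

    # --- founder-het filter (homozygosity-mapping markers) ---------------
    founder_kept, filt_report = filter_founder_het(
        data.founder_wgs, cfg.filters, scaffold_lengths)
    report["filter"] = {
        "n_in": int(data.founder_wgs.n_variants),
        "n_kept": int(founder_kept.n_variants),
        "n_removed": int(len(filt_report)),
    }

    # --- pooled homozygosity mapping -------------------------------------
    keys = founder_kept.variants[["scaffold", "pos", "ref", "alt"]]
    pools = data.pool_counts.merge(keys, on=list(keys.columns), how="inner")
    windows = window_scan(pools, cfg.rule, cfg.window_size, cfg.min_variants,
                          scaffold_lengths)
    ranked_all, hist = rank_candidates(windows, top_k=max(cfg.top_k, len(windows)))
    ranked = ranked_all.head(cfg.top_k)
    qual = windows[windows["qualifying"]]
    report["hommap"] = {
        "n_variants": int(len(pools)),
        "n_windows": int(len(windows)),
        "n_qualifying": int(len(qual)),
        "top_windows": ranked.head(5).to_dict("records"),
        "fraction_hist_counts": hist[0].tolist(),
        "genome_wide_mean_fraction": float(qual["fraction"].mean()),
    }

    # --- kinship-corrected association scan -------------------------------
    rad = mask_low_quality_calls(data.rad, cfg.filters)
    dosage = rad.dosage_matrix()
    keep = filter_association_markers(dosage, cfg.filters)
    g = dosage[:, keep]
    meta = rad.variants.loc[keep, ["scaffold", "pos"]].reset_index(drop=True)
    pheno = data.phenotypes.set_index("id")["phenotype"]
    y = pheno.loc[rad.samples].to_numpy(float)
    kin = compute_kinship(g)
    vc, ctx = fit_null_variance_components(y, kin)
    assoc = association_scan(y, g, kin, meta, lam=ctx["lam"])
    meff = effective_tests(g)
    thr = fwer_threshold(cfg.alpha, meff)
    sig = assoc[assoc["tested"] & (assoc["p"] < thr)]
    report["assoc"] = {
        "n_markers_in": int(dosage.shape[1]),
        "n_markers_tested": int(keep.sum()),
        "sigma_g2": float(vc.sigma_g2),
        "sigma_e2": float(vc.sigma_e2),
        "lambda": float(ctx["lam"]),
        "m_eff": float(meff),
        "alpha": cfg.alpha,
        "threshold": float(thr),
        "n_significant_markers": int(len(sig)),
        "n_significant_scaffolds": int(sig["scaffold"].nunique()),
    }

    # --- synteny ordering and LD decay ------------------------------------
    tested = assoc[assoc["tested"]].sort_values("p", kind="mergesort")
    panel = tested.head(cfg.ld_markers)
    panel_idx = panel.index.to_numpy()
    ordered = project_markers(meta.loc[panel_idx], data.anchors)
    ordered.insert(0, "p", assoc.loc[panel_idx, "p"].to_numpy())
    r2 = ld_matrix(g, panel_idx)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    try:
        decay = ld_decay(r2, ordered["ref_pos"].to_numpy(float),
                         cfg.ld_permutations, rng)
    except ValueError as exc:
        decay = {"statistic": np.nan, "p_value": np.nan, "error": str(exc)}
    report["synteny_ld"] = {
        "n_panel_markers": int(len(panel)),
        "n_placed": int(ordered["placed"].sum()),
        "decay": decay,
    }

    # --- truth comparison --------------------------------------------------
    t = data.truth
    rank = causal_window_rank(ranked_all, t.causal_scaffold,
                              t.causal_scaffold_pos, cfg.window_size)
    near = qual[(qual["scaffold"] == t.causal_scaffold)
                & (qual["start"] >= t.causal_scaffold_pos - 1 - 50_000)
                & (qual["end"] <= t.causal_scaffold_pos - 1 + 50_000 + cfg.window_size)]
    top_marker = tested.iloc[0] if len(tested) else None
    report["truth"] = {
        "causal_scaffold": t.causal_scaffold,
        "causal_pos": int(t.causal_scaffold_pos),
        "causal_window_rank": rank,
        "near_causal_mean_fraction": float(near["fraction"].mean()) if len(near) else None,
        "top_marker_scaffold": None if top_marker is None else str(top_marker["scaffold"]),
        "top_marker_distance_to_causal": (
            int(abs(top_marker["pos"] - t.causal_scaffold_pos))
            if top_marker is not None and top_marker["scaffold"] == t.causal_scaffold
            else None),
    }

    return PipelineResult(_jsonify(report), data, assoc, windows, ranked,
                          ordered, r2, filt_report)


def run_pipeline(cfg: RunConfig, outdir=None) -> PipelineResult:
    """Simulate a colony under ``cfg`` and run the full analysis.

    When ``outdir`` is given, all stage inputs/outputs are written there
    as plain VCF/TSV/BED files plus ``report.json`` and a serialized copy
    of the configuration.
    """
    data = simulate_colony(cfg.colony)
    result = analyze_colony(data, cfg)
    if outdir is not None:
        write_outputs(result, cfg, Path(outdir))
    return result


def write_outputs(result: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    data = result.data
    lengths = data.scaffold_lengths
    cfg.to_yaml(outdir / "config.yaml")
    fio.write_vcf(data.rad, outdir / "rad.vcf", lengths)
    fio.write_vcf(data.founder_wgs, outdir / "founder.vcf", lengths)
    fio.write_pool_vcf(data.pool_counts, outdir / "pools.vcf", lengths)
    fio.write_table(data.phenotypes, outdir / "pedigree.tsv")
    fio.write_table(data.anchors, outdir / "anchors.tsv")
    fio.write_table(lengths, outdir / "scaffold_lengths.tsv")
    fio.write_table(data.truth.individuals_frame(), outdir / "truth_individuals.tsv")
    fio.write_table(result.filter_report, outdir / "filter_report.tsv")
    fio.write_table(result.association, outdir / "association.tsv")
    fio.write_table(result.windows, outdir / "windows.tsv")
    bed = result.windows[["scaffold", "start", "end", "n_informative",
                          "n_concordant", "fraction"]]
    bed.to_csv(outdir / "windows.bed", sep="\t", index=False, header=False)
    fio.write_table(result.ranked_windows, outdir / "ranked_windows.tsv")
    fio.write_table(result.ordered_markers, outdir / "ordered_markers.tsv")
    np.savetxt(outdir / "ld_matrix.tsv", result.ld_r2, delimiter="\t", fmt="%.6g")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
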