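"""End-to-end orchestration: simulate -> distances -> clones/MDS -> AIMs ->
local ancestry -> IBD/relatedness, with a manifest and optional figures.

The pipeline is driven by a :class:`RunConfig` (loadable from YAML with a
strict schema). Every threshold is echoed into the output manifest together
with the seed and a SHA-256 of each table, so a rerun with the same config
and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import divergence as div
from . import relatedness as rel
from . import structure as struct
from .genotypes import VariantMatrix, make_windows, read_vcf
from .sim import (
    Clone,
    Cross,
    Founder,
    Introgressed,
    PedigreeSpec,
    PopulationModel,
    build_cohort,
    emit_dataset,
)

__all__ = ["RunConfig", "run_end_to_end", "render_report", "demo_pedigree"]

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "vcf", "window_bp", "het_window_sites", "aim_window",
    "min_aims_per_pop", "ibsr_threshold", "d_threshold", "mismatch_threshold",
    "clone_threshold", "epsilon", "margin_threshold", "min_informative",
    "exemplars", "pairs", "hybrids", "simulate", "make_figures",
}


@dataclass
class RunConfig:
    """Configuration for a full run. All thresholds are recorded in the manifest."""

    seed: int
    out_dir: str
    vcf: str | None = None  # mutually exclusive with simulate
    simulate: bool = True
    window_bp: int = 200_000
    het_window_sites: int = 500_000
    aim_window: int = 500
    min_aims_per_pop: int = 5
    ibsr_threshold: float = rel.DEFAULT_IBSR_THRESHOLD
    d_threshold: float = rel.DEFAULT_D_THRESHOLD
    mismatch_threshold: float = rel.DEFAULT_MISMATCH_THRESHOLD
    clone_threshold: float = struct.DEFAULT_CLONE_THRESHOLD
    epsilon: float = 0.01
    margin_threshold: float = 2.0
    min_informative: int = rel.DEFAULT_MIN_INFORMATIVE
    #: population -> exemplar sample ids (required when the ancestry stage runs)
    exemplars: dict[str, list[str]] = field(default_factory=dict)
    #: sample pairs for IBD/relatedness analysis
    pairs: list[tuple[str, str]] = field(default_factory=list)
    #: hybrid -> (panelA pop, panelB pop) for interspecific phasing
    hybrids: dict[str, tuple[str, str]] = field(default_factory=dict)
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        if "pairs" in raw:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        if "hybrids" in raw:
            raw["hybrids"] = {k: tuple(v) for k, v in raw["hybrids"].items()}
        return cls(**raw)

    def validate(self) -> None:
        if self.vcf is None and not self.simulate:
            raise ValueError("either an input VCF or the simulation stage is required")
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")


def demo_pedigree(model: PopulationModel) -> PedigreeSpec:
    """The demo family: a half-sib F1 family with one shared, introgressed
    mandarin parent, plus clones and population panels.

    Structure: three RK and three MA founders serve as exemplar panels (plus
    MS and PU panels for AIM derivation); one extra MA-background individual
    carrying a single 2.4-Mbp PU segment ('shared_parent') is crossed to six
    distinct RK founders, yielding six half-sib F1s; one F1 has an apomictic
    clone with light somatic mutation.
    """
    chrom = model.chrom_names[0]
    entries: list = []
    for pop in model.populations:
        for i in range(3 if pop != "MS" else 2):
            entries.append(Founder(f"{pop}{i + 1}", pop, depth=30.0 + i))
    # one introgressed donor segment, 2.4 Mbp when the chromosome allows it
    seg_start = model.chrom_length // 6
    seg_end = min(seg_start + 2_400_000, model.chrom_length)
    entries.append(Introgressed(
        "shared_parent", pop="MA", donor="PU",
        segments=[(chrom, seg_start, seg_end)], depth=46.0,
    ))
    for i in range(6):
        entries.append(Founder(f"RKp{i + 1}", "RK", depth=25.0))
        entries.append(Cross(f"F1_{i + 1}", f"RKp{i + 1}", "shared_parent", depth=35.0))
    entries.append(Clone("F1_1_clone", "F1_1", somatic_rate=1e-4, depth=20.0))
    return PedigreeSpec(entries)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(
    config: RunConfig,
    model: PopulationModel | None = None,
    pedigree: PedigreeSpec | None = None,
) -> dict[str, Any]:
    """Run every stage and write tables + manifest under ``config.out_dir``.

    Returns a dict with the in-memory stage results (matrix, truth, tables)
    and the manifest. Raises on the first failing stage, naming it.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("window_bp", "het_window_sites", "aim_window",
                      "min_aims_per_pop", "ibsr_threshold", "d_threshold",
                      "mismatch_threshold", "clone_threshold", "epsilon",
                      "margin_threshold", "min_informative")
        },
        "stages": {},
        "outputs": {},
    }
    results: dict[str, Any] = {"manifest": manifest}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        return deco

    def emit(name: str, df: pd.DataFrame, fname: str) -> None:
        path = out / fname
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = {"path": fname, "sha256": _sha256(path)}

    # --- input ---
    @stage("input")
    def _():
        nonlocal model, pedigree
        if config.simulate and config.vcf is None:
            m = model or PopulationModel()
            ped = pedigree or demo_pedigree(m)
            matrix, truth = build_cohort(m, ped, config.seed)
            emit_dataset(matrix, truth, out / "dataset")
            results["matrix"], results["truth"] = matrix, truth
            results["model"] = m
        else:
            results["matrix"] = read_vcf(config.vcf)
            results["truth"] = None
        if config.exemplars:
            known = set(results["matrix"].sample_ids)
            missing = {s for ss in config.exemplars.values() for s in ss} - known
            if missing:
                raise ValueError(f"exemplar samples not in cohort: {sorted(missing)}")

    matrix: VariantMatrix = results["matrix"]
    samples = matrix.sample_ids

    # --- distances, clones, MDS ---
    @stage("structure")
    def _():
        dmat = struct.pairwise_distance_matrix(matrix)
        emit("distance_matrix", dmat.to_frame().reset_index(names="sample"),
             "distance_matrix.tsv")
        depth = (matrix.samples["depth"].tolist()
                 if "depth" in matrix.samples else None)
        clones = struct.collapse_clones(dmat, depth, config.clone_threshold)
        emit("clone_groups", clones, "clone_groups.tsv")
        results["dmat"], results["clones"] = dmat, clones
        reps = clones[clones["is_representative"]]["sample"].tolist()
        if len(reps) >= 4:
            sub = struct.pairwise_distance_matrix(matrix, reps)
            mds = struct.classical_mds(sub, k=min(3, len(reps) - 1))
            emit("mds", mds.to_frame().reset_index(names="sample"), "mds.tsv")
            results["mds"] = mds

    # --- heterozygosity ---
    @stage("heterozygosity")
    def _():
        frame = make_windows(matrix, "callable_count", config.het_window_sites)
        tables = []
        for s in samples:
            t = div.heterozygosity_windows(matrix, s, frame)
            t.insert(0, "sample", s)
            tables.append(t)
        emit("heterozygosity", pd.concat(tables, ignore_index=True),
             "heterozygosity.tsv")

    # --- ancestry ---
    if config.exemplars:
        @stage("ancestry")
        def _():
            aims = anc.derive_aims(matrix, config.exemplars)
            emit("aims", aims.table, "aims.tsv")
            tracks, prop_rows, seg_tables = {}, [], []
            exemplar_ids = {s for ss in config.exemplars.values() for s in ss}
            for s in samples:
                if s in exemplar_ids:
                    continue
                track = anc.window_ancestry(
                    matrix, s, aims, window_size=config.aim_window,
                    epsilon=config.epsilon,
                    min_aims_per_pop=config.min_aims_per_pop,
                    margin_threshold=config.margin_threshold,
                )
                tracks[s] = track
                prop_rows.append({"sample": s, **track.proportions,
                                  "Unknown": track.unknown_fraction})
                segs = anc.merge_segments(track)
                segs.insert(0, "sample", s)
                seg_tables.append(segs)
            emit("admixture_proportions", pd.DataFrame(prop_rows),
                 "admixture_proportions.tsv")
            if seg_tables:
                emit("ancestry_segments", pd.concat(seg_tables, ignore_index=True),
                     "ancestry_segments.tsv")
            results["tracks"] = tracks
            results["aims"] = aims

    # --- interspecific phasing / haplotype sharing ---
    if config.hybrids:
        @stage("phasing")
        def _():
            if not config.exemplars:
                raise ValueError("phasing needs exemplar panels")
            frame = make_windows(matrix, "bp_span", config.window_bp)
            res_rows, share_rows = [], []
            phased = {}
            for hyb, (pop_a, pop_b) in config.hybrids.items():
                ph = rel.interspecific_phase(
                    matrix, hyb, config.exemplars[pop_a], config.exemplars[pop_b]
                )
                phased[hyb] = ph
                res_rows.append({
                    "sample": hyb, "panel_a": pop_a, "panel_b": pop_b,
                    "phased": float((ph.status == "phased").mean()),
                    "homozygous": float((ph.status == "homozygous").mean()),
                    "unresolved": ph.unresolved_fraction,
                })
            hybs = list(phased)
            for i, h1 in enumerate(hybs):
                for h2 in hybs[i + 1:]:
                    t = rel.haplotype_identity(
                        phased[h1].hap_b, phased[h2].hap_b, frame,
                        threshold=config.mismatch_threshold,
                    )
                    ok = t["defined"]
                    share_rows.append({
                        "sample1": h1, "sample2": h2,
                        "identical_window_fraction":
                            float(t.loc[ok, "identical"].mean()) if ok.any() else np.nan,
                        "n_windows": int(ok.sum()),
                    })
            emit("phasing_summary", pd.DataFrame(res_rows), "phasing_summary.tsv")
            if share_rows:
                emit("haplotype_sharing", pd.DataFrame(share_rows),
                     "haplotype_sharing.tsv")
            results["phased"] = phased

    # --- relatedness ---
    pairs = config.pairs or [
        (a, b) for i, a in enumerate(samples) for b in samples[i + 1:]
    ]
    @stage("relatedness")
    def _():
        frame = make_windows(matrix, "bp_span", config.window_bp)
        rows, win_tables = [], []
        for s1, s2 in pairs:
            res = rel.pair_ibd(
                matrix, s1, s2, frame,
                min_informative=config.min_informative,
                ibsr_threshold=config.ibsr_threshold,
                d_threshold=config.d_threshold,
            )
            rows.append((s1, s2, res.ibd0, res.ibd1, res.ibd2, res.r,
                         res.n_classified))
            t = res.table.copy()
            t.insert(0, "pair", f"{s1}|{s2}")
            win_tables.append(t)
        summary = pd.DataFrame(
            rows, columns=["sample1", "sample2", "ibd0", "ibd1", "ibd2", "r",
                           "n_windows"])
        emit("relatedness_summary", summary, "relatedness_summary.tsv")
        emit("relatedness_windows", pd.concat(win_tables, ignore_index=True),
             "relatedness_windows.tsv")
        results["relatedness"] = summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def render_report(results: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Render figures and a text summary from stage outputs.

    Produces an MDS scatter, per-sample admixture stacked bars and a
    heterozygosity distribution figure where the corresponding stages ran;
    missing stages are noted and skipped. Returns the summary path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix: VariantMatrix | None = results.get("matrix")
    if matrix is None or matrix.n_samples == 0:
        raise ValueError("no cohort to report on")

    notices = []

    if "mds" in results:
        mds = results["mds"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(mds.coordinates[:, 0], mds.coordinates[:, 1], s=18)
        for name, (x, y) in zip(mds.samples, mds.coordinates[:, :2]):
            ax.annotate(name, (x, y), fontsize=6)
        ax.set_xlabel("PCo 1")
        ax.set_ylabel("PCo 2")
        fig.tight_layout()
        fig.savefig(out / "mds.png", dpi=120)
        plt.close(fig)
    else:
        notices.append("MDS stage missing: scatter omitted")

    if "tracks" in results and results["tracks"]:
        tracks = results["tracks"]
        pops = list(next(iter(tracks.values())).proportions)
        names = list(tracks)
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(names)), 3.5))
        bottom = np.zeros(len(names))
        for pop in pops:
            vals = np.array([np.nan_to_num(tracks[s].proportions[pop])
                             for s in names])
            ax.bar(names, vals, bottom=bottom, label=pop)
            bottom += vals
        ax.set_ylabel("ancestry proportion")
        ax.legend(fontsize=7)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / "admixture.png", dpi=120)
        plt.close(fig)
    else:
        notices.append("ancestry stage missing: admixture bars omitted")

    lines = ["sample summary", "=============="]
    rel_summary: pd.DataFrame | None = results.get("relatedness")
    tracks = results.get("tracks", {})
    for s in matrix.sample_ids:
        parts = [s]
        if tracks and s in tracks:
            props = tracks[s].proportions
            top = max(props, key=lambda p: np.nan_to_num(props[p]))
            parts.append(
                "ancestry: " + ", ".join(f"{p}={props[p]:.2f}" for p in props)
                + f" (top {top})"
            )
        if rel_summary is not None:
            mine = rel_summary[(rel_summary["sample1"] == s)
                               | (rel_summary["sample2"] == s)]
            if len(mine):
                best = mine.sort_values("r", ascending=False).head(3)
                rels = [
                    f"{(r.sample2 if r.sample1 == s else r.sample1)} (r={r.r:.2f})"
                    for r in best.itertuples()
                ]
                parts.append("top relatives: " + ", ".join(rels))
        lines.append(" | ".join(parts))
    if notices:
        lines += ["", "notices:"] + [f"- {n}" for n in notices]
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
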