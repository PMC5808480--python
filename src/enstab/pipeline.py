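"""End-to-end orchestration: structures -> ensembles -> SEA -> destructive,
plus the stiffness branch and optional survival/conservation correlations.

Every intermediate table is written to the output directory; a run manifest
records the configuration, seeds and an input-content hash so reruns are
auditable.  Rerunning into an existing output directory requires ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import destructive as dmod
from . import stats
from .enm import EnsembleConfig, build_elastic_model, compute_modes, generate_conformers
from .hbond_sea import compute_sea_table, DEFAULT_ANGLE_CUTOFF, DEFAULT_DIST_CUTOFF
from .stiffness import mean_stiffness, pairwise_stiffness, site_stiffness_profile, top_tail
from .structure_io import Structure, read_pdb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structures: dict[str, str]  # id -> PDB path
    wt_id: str
    out_dir: str
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    hbond_dist_cutoff: float = DEFAULT_DIST_CUTOFF
    hbond_angle_cutoff: float = DEFAULT_ANGLE_CUTOFF
    destructive_tail: float = 0.05
    counting_policy: str = "variant_present_bonds"
    stiffness_node_policy: str = "calpha"
    stiffness_site: tuple[str, int] | None = None  # (chain, residue number) of a metal node
    tail_mean: float = 0.0017
    tail_site: float = 0.0065
    survival_table: str | None = None  # TSV: mutation <TAB> years
    variant_positions: dict[str, int] | None = None  # variant id -> mutated position
    seed: int = 0
    force: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "ensemble" in raw:
            raw["ensemble"] = EnsembleConfig(**raw["ensemble"])
        if raw.get("stiffness_site") is not None:
            raw["stiffness_site"] = tuple(raw["stiffness_site"])
        return cls(**raw)

    def validate(self) -> None:
        if self.wt_id not in self.structures:
            raise ValueError(f"wild-type id {self.wt_id!r} not among structures")
        for sid, p in self.structures.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"structure {sid}: {p}")
        if self.survival_table and not Path(self.survival_table).exists():
            raise FileNotFoundError(self.survival_table)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        cfg = asdict(self)
        cfg.pop("force", None)
        h.update(json.dumps(cfg, sort_keys=True, default=str).encode())
        for sid in sorted(self.structures):
            h.update(Path(self.structures[sid]).read_bytes())
        return h.hexdigest()[:16]


@dataclass
class PipelineReport:
    out_dir: Path
    summary: dict

    def __getitem__(self, key):
        return self.summary[key]


def run_pipeline(
    config: PipelineConfig,
    structures: Mapping[str, Structure] | None = None,
) -> PipelineReport:
    """Run every stage whose inputs are available and write a report bundle.

    ``structures`` may supply in-memory structures directly (the paths in the
    config are then ignored); otherwise PDB files are read.  Stages: conformer
    ensembles, SEA table, mean-shift clustering of SEA columns, H-table /
    destructive-bond detection, stiffness maps for the wild type, and — when a
    survival table plus variant-position map is configured — the
    stiffness-survival correlation.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    from_files = structures is None
    if structures is None:
        config.validate()
        structures = {sid: read_pdb(p, identifier=sid) for sid, p in config.structures.items()}
    if config.wt_id not in structures:
        raise ValueError(f"wild-type id {config.wt_id!r} missing")

    summary: dict = {"stages": {}}

    # --- ensembles + SEA ---
    ensembles = {}
    for sid, s in structures.items():
        model = build_elastic_model(s, config.ensemble)
        modes = compute_modes(model, config.ensemble.n_modes)
        ensembles[sid] = generate_conformers(s, modes, config.ensemble)
    summary["stages"]["ensembles"] = {
        "n_structures": len(ensembles),
        "conformers_per_structure": len(next(iter(ensembles.values()))),
        "total_conformers": sum(len(e) for e in ensembles.values()),
    }
    sea = compute_sea_table(
        ensembles, config.wt_id, config.hbond_dist_cutoff, config.hbond_angle_cutoff
    )
    sea.to_tsv(out / "sea.tsv")
    summary["stages"]["sea"] = {"n_bonds": len(sea.bonds), "n_structures": len(sea.structures)}

    # --- mean-shift clustering of structures by SEA profile ---
    points = sea.values.T.to_numpy()
    cluster_section: dict = {"run": False}
    if points.shape[0] >= 2:
        try:
            bw = stats.estimate_bandwidth(points)
            clust = stats.mean_shift(points, bw)
            labels = pd.Series(clust.labels, index=sea.structures, name="cluster")
            labels.to_csv(out / "clusters.tsv", sep="\t")
            cluster_section = {
                "run": True,
                "bandwidth": bw,
                "n_clusters": clust.n_clusters,
                "labels": labels.to_dict(),
            }
        except ValueError as exc:
            logger.warning("SEA clustering skipped: %s", exc)
    summary["stages"]["clustering"] = cluster_section

    # --- destructive bonds ---
    dest_section: dict = {"run": False}
    if sea.variants:
        contrib = dmod.compute_deviations(sea)
        pd.DataFrame({"D": contrib.D}).to_csv(out / "deviations.tsv", sep="\t")
        htab = dmod.build_h_table(contrib, config.counting_policy)
        htab.to_tsv(out / "h_table.tsv")
        pd.DataFrame({"S_H": htab.s_bar()}).to_csv(out / "s_bar.tsv", sep="\t")
        if len(htab.variants) >= 2:
            selected, _ = dmod.select_high_contribution_variants(htab)
        else:
            selected = set()
        if selected:
            result = dmod.detect_destructive(contrib, selected, config.destructive_tail)
            result.to_frame().to_csv(out / "destructive_bonds.tsv", sep="\t")
            res_df = dmod.residues_of_bonds(result.destructive_bonds)
            res_df.to_csv(out / "destructive_residues.tsv", sep="\t", index=False)
            dest_section = {
                "run": True,
                "selected_variants": sorted(selected),
                "n_destructive": len(result.destructive_bonds),
                "threshold": result.threshold,
                "explained_fraction": result.explained_fraction,
                "destructive_bonds": result.destructive_bonds,
            }
        else:
            dest_section = {"run": True, "selected_variants": [], "n_destructive": 0}
    summary["stages"]["destructive"] = dest_section

    # --- stiffness branch (wild type) ---
    from .enm import EnsembleConfig as _EC

    stiff_cfg = _EC(
        n_modes=config.ensemble.n_modes,
        cutoff=config.ensemble.cutoff,
        gamma=config.ensemble.gamma,
        node_policy=config.stiffness_node_policy,  # type: ignore[arg-type]
    )
    wt = structures[config.wt_id]
    model = build_elastic_model(wt, stiff_cfg)
    modes = compute_modes(model)
    stiff = pairwise_stiffness(modes)
    stiff.to_frame().to_csv(out / "kappa.tsv", sep="\t")
    kbar = mean_stiffness(stiff)
    kbar_df = pd.DataFrame(
        {"chain": [c for c, _ in kbar.index], "residue": [r for _, r in kbar.index], "K_bar": kbar.values}
    )
    kbar_df.to_csv(out / "mean_stiffness.tsv", sep="\t", index=False)
    top_mean = top_tail(kbar, config.tail_mean)
    stiff_section = {
        "run": True,
        "n_nodes": stiff.n,
        "top_mean_stiffness": sorted(f"{c}:{r}" for c, r in top_mean),
    }
    if config.stiffness_site is not None:
        profile = site_stiffness_profile(stiff, tuple(config.stiffness_site))
        prof_df = pd.DataFrame(
            {"chain": [c for c, _ in profile.index], "residue": [r for _, r in profile.index], "kappa_site": profile.values}
        )
        prof_df.to_csv(out / "site_stiffness.tsv", sep="\t", index=False)
        finite = profile[np.isfinite(profile.values)]
        stiff_section["top_site_stiffness"] = sorted(
            f"{c}:{r}" for c, r in top_tail(finite, config.tail_site)
        )
    summary["stages"]["stiffness"] = stiff_section

    # --- survival correlation ---
    surv_section: dict = {"run": False}
    if config.survival_table and config.variant_positions:
        surv = pd.read_csv(config.survival_table, sep="\t")
        kappa_vals, years = [], []
        for _, row in surv.iterrows():
            v = str(row["mutation"])
            pos = config.variant_positions.get(v)
            if pos is None:
                continue
            key = next((nid for nid in kbar.index if nid[1] == pos), None)
            if key is None:
                continue
            kappa_vals.append(kbar[key])
            years.append(float(row["years"]))
        if len(kappa_vals) >= 3:
            r, p = stats.pearson(kappa_vals, years)
            surv_section = {"run": True, "n": len(kappa_vals), "R": r, "p": p}
            pd.DataFrame({"kappa": kappa_vals, "years": years}).to_csv(
                out / "survival_correlation.tsv", sep="\t", index=False
            )
    summary["stages"]["survival"] = surv_section

    summary["wall_time_s"] = round(time.time() - t_start, 3)
    manifest = {
        "config_hash": None,
        "seed": config.seed,
        "n_structures": len(structures),
        "wall_time_s": summary["wall_time_s"],
    }
    if from_files:
        manifest["config_hash"] = config.content_hash()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    _write_text_summary(out / "summary.txt", summary)
    return PipelineReport(out_dir=out, summary=summary)


def _write_text_summary(path: Path, summary: dict) -> None:
    lines = ["enstab pipeline summary", "=" * 30]
    for stage, info in summary["stages"].items():
        lines.append(f"\n[{stage}]")
        if isinstance(info, dict):
            for k, v in info.items():
                if isinstance(v, (list, dict)) and len(str(v)) > 200:
                    v = f"<{len(v)} items>"
                lines.append(f"  {k}: {v}")
    lines.append(f"\nwall time: {summary['wall_time_s']} s")
    path.write_text("\n".join(lines) + "\n")
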