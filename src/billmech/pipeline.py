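"""End-to-end comparative excavation analysis.

From one config: generate the synthetic clade, mesh every species, run the
six FE solves per species ({impact, torsion} x {composite, all_keratin,
all_bone}), compute beam-theory metrics from measured base dimensions,
then the comparative statistics (Spearman + PGLS suite, composite-vs-
homogeneous paired tests) and the exportable tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import beams, fem, geometry, io, phylo

__all__ = ["RunConfig", "RunReport", "run_full_analysis", "make_fig_tables"]

log = logging.getLogger("billmech")

MATERIAL_MODES = ("composite", "all_keratin", "all_bone")
REGIMES = ("impact", "torsion")

#: (n_axial, n_circumferential) refinement ladder: the cross-sectional
#: discretization is held fixed so its error cancels between levels while
#: the axial profile (the slowly converging direction for both loading
#: regimes) is refined
DEFAULT_CONVERGENCE_LADDER = [(10, 16), (14, 16), (20, 16), (28, 16), (40, 16)]


@dataclass
class RunConfig:
    """Full configuration of one analysis run (serialised for provenance)."""

    seed: int = 0
    output_dir: str | None = None
    verbosity: int = 1
    export_fields: bool = False  # write per-solve VTK heat maps
    run_convergence: bool = False
    geometry: dict = field(default_factory=lambda: {
        "n_axial": 20,
        "n_circumferential": 16,
        "tip_fraction": 0.05,
        "zone_center_fraction": 2.0 / 3.0,
        "zone_half_width_fraction": 0.005,
        "basal_slice_fraction": 0.02,
    })
    clade: dict = field(default_factory=lambda: {
        "n_species": 15,
        "split": (7, 8),
        "trait_params": None,
    })
    loads: dict = field(default_factory=lambda: {"F": 10.0, "theta": 1.75e-3})
    materials: dict = field(default_factory=lambda: {
        "keratin": {"E": 6.5e9, "nu": 0.4, "rho": 1000.0},
        "bone": {"E": 12.7e9, "nu": 0.4, "rho": 50.0},
    })
    fem: dict = field(default_factory=lambda: {
        "resolutions": DEFAULT_CONVERGENCE_LADDER,
    })
    beams: dict = field(default_factory=lambda: {"n_grid": 25})

    def __post_init__(self) -> None:
        self.clade["split"] = tuple(self.clade.get("split", (7, 8)))
        if self.clade["split"][0] + self.clade["split"][1] != self.clade.get("n_species", 15):
            raise ValueError("clade split must sum to n_species")
        if self.loads["F"] <= 0 or self.loads["theta"] <= 0:
            raise ValueError("loads must be positive")
        if self.geometry["n_axial"] < 4 or self.geometry["n_circumferential"] < 8:
            raise ValueError("geometry resolution too coarse")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        cfg.__post_init__()
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        data = asdict(self)
        data["clade"]["split"] = list(data["clade"]["split"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def keratin(self) -> fem.Material:
        k = self.materials["keratin"]
        return fem.Material("keratin", k["E"], k["nu"], k["rho"])

    def bone(self) -> fem.Material:
        b = self.materials["bone"]
        return fem.Material("bone", b["E"], b["nu"], b["rho"])


@dataclass
class RunReport:
    """All computed results of one run."""

    config: RunConfig
    clade: geometry.CladeSample
    species_results: pd.DataFrame  # species x regime x material mode peak VM
    comparative_table: pd.DataFrame
    correlation_suite: pd.DataFrame
    composite_comparison: pd.DataFrame
    performance_grid: pd.DataFrame
    convergence: pd.DataFrame | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _solve(mesh, assignment, regime, loads):
    if regime == "impact":
        return fem.solve_impact(mesh, assignment, fem.LoadCase("impact", F=loads["F"]))
    return fem.solve_torsion(mesh, assignment, fem.LoadCase("torsion", theta=loads["theta"]))


def run_full_analysis(config: RunConfig) -> RunReport:
    """Run the whole pipeline; deterministic under ``config.seed``."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    if config.verbosity:
        logging.basicConfig(level=logging.INFO, format="%(message)s")

    clade = geometry.generate_clade(
        n_species=config.clade["n_species"],
        split=config.clade["split"],
        trait_params=config.clade.get("trait_params"),
        seed=config.seed,
    )
    timings["clade"] = time.perf_counter() - t0
    log.info("clade: %d species in %.2fs", clade.phylogeny.n_tips, timings["clade"])

    g = config.geometry
    assignments = {
        mode: fem.material_assignment(mode, keratin=config.keratin(), bone=config.bone())
        for mode in MATERIAL_MODES
    }
    kmat = config.keratin()

    records, table_rows = [], []
    stage = time.perf_counter()
    for label in clade.phylogeny.tip_labels:
        spec = clade.specs[label]
        try:
            mesh = geometry.make_bill_mesh(spec, g["n_axial"], g["n_circumferential"])
            mesh = geometry.tag_node_sets(
                mesh, g["tip_fraction"], g["zone_center_fraction"], g["zone_half_width_fraction"]
            )
            width, depth = geometry.measure_base_dimensions(mesh, g["basal_slice_fraction"])
            peaks = {}
            for regime in REGIMES:
                for mode in MATERIAL_MODES:
                    f = _solve(mesh, assignments[mode], regime, config.loads)
                    peak = fem.peak_vm_in_zone(f, mesh)
                    peaks[(regime, mode)] = peak
                    records.append({
                        "species": label, "regime": regime, "material_mode": mode,
                        "element_count": mesh.n_tets, "peak_vm": peak,
                    })
                    if outdir and config.export_fields:
                        io.write_vtk(mesh, outdir / f"{label}_{regime}_{mode}.vtk",
                                     point_data={"nodal_vm": f.nodal_vm})
            bm = beams.beam_metrics(
                kmat.E, kmat.nu, config.loads["theta"],
                beams.BeamGeometry(a=width / 2, b=depth / 2, L=spec.length),
            )
            table_rows.append({
                "species": label,
                "peak_vm_impact": peaks[("impact", "composite")],
                "peak_vm_torsion": peaks[("torsion", "composite")],
                "sigma_cr": bm.sigma_cr,
                "tau_max": bm.tau_max,
                "width": width,
                "depth": depth,
                "body_length": clade.body_length[label],
            })
        except Exception as exc:
            raise RuntimeError(f"FE stage failed for species {label!r}: {exc}") from exc
    species_results = pd.DataFrame(records)
    table = pd.DataFrame(table_rows).set_index("species")
    timings["fem"] = time.perf_counter() - stage
    log.info("FE: %d solves in %.2fs", len(records), timings["fem"])

    stage = time.perf_counter()
    suite = phylo.run_correlation_suite(table, clade.phylogeny)
    comparison = composite_comparison(species_results, clade.phylogeny)
    timings["stats"] = time.perf_counter() - stage

    a_half, b_half = table["width"] / 2, table["depth"] / 2
    A, B, sig, tau = beams.performance_grid(
        (0.8 * a_half.min(), 1.2 * a_half.max()),
        (0.8 * b_half.min(), 1.2 * b_half.max()),
        kmat.E, kmat.nu, config.loads["theta"], 0.05, config.beams["n_grid"],
    )
    grid = beams.grid_to_frame(A, B, sig, tau)

    convergence = None
    if config.run_convergence:
        stage = time.perf_counter()
        convergence = fem.convergence_study(
            geometry.BillSpec(), assignments["composite"],
            fem.LoadCase("impact", F=config.loads["F"]),
            [tuple(r) for r in config.fem["resolutions"]],
        )
        timings["convergence"] = time.perf_counter() - stage

    timings["total"] = time.perf_counter() - t0
    report = RunReport(
        config=config, clade=clade, species_results=species_results,
        comparative_table=table, correlation_suite=suite,
        composite_comparison=comparison, performance_grid=grid,
        convergence=convergence, timings=timings,
    )
    if outdir:
        _write_outputs(report, outdir)
    return report


def composite_comparison(species_results: pd.DataFrame, tree: phylo.Phylogeny) -> pd.DataFrame:
    """Composite-vs-homogeneous paired comparison per regime and material.

    Percentage difference = 100 (VM_homogeneous - VM_composite) / VM_composite,
    so a positive median means the composite performs better (lower stress).
    """
    if species_results.empty:
        raise ValueError("empty species results")
    wide = species_results.pivot_table(
        index="species", columns=["regime", "material_mode"], values="peak_vm"
    ).loc[tree.tip_labels]
    rows = []
    for regime in REGIMES:
        comp = wide[(regime, "composite")]
        for mode in ("all_keratin", "all_bone"):
            homo = wide[(regime, mode)]
            pct = 100.0 * (homo - comp) / comp
            try:
                w_p = phylo.wilcoxon_signed_rank(homo.to_numpy(), comp.to_numpy())
            except ValueError:
                w_p = np.nan
            try:
                t_res = phylo.phyl_paired_ttest(homo, comp, tree)
                t_p, t_lam = t_res.p_value, t_res.lambda_
            except ValueError:
                t_p, t_lam = np.nan, np.nan
            rows.append({
                "regime": regime, "homogeneous_material": mode.removeprefix("all_"),
                "median_pct_difference": float(pct.median()),
                "wilcoxon_p": w_p, "phyl_paired_t_p": t_p, "phyl_paired_t_lambda": t_lam,
            })
    return pd.DataFrame(rows)


def _write_outputs(report: RunReport, outdir: Path) -> None:
    report.species_results.to_csv(outdir / "species_results.csv", index=False)
    report.comparative_table.to_csv(outdir / "comparative_table.csv")
    report.correlation_suite.to_csv(outdir / "correlation_suite.csv", index=False)
    report.composite_comparison.to_csv(outdir / "composite_comparison.csv", index=False)
    report.performance_grid.to_csv(outdir / "performance_grid.csv", index=False)
    if report.convergence is not None:
        report.convergence.to_csv(outdir / "convergence.csv", index=False)
    phylo.write_newick(report.clade.phylogeny, outdir / "clade.nwk")
    stats = {
        "seed": report.config.seed,
        "timings_s": {k: round(v, 3) for k, v in report.timings.items()},
        "n_species": report.clade.phylogeny.n_tips,
        "n_solves": len(report.species_results),
    }
    (outdir / "run_stats.json").write_text(json.dumps(stats, indent=2))
    summary = _summary_text(report)
    (outdir / "summary.txt").write_text(summary)
    make_fig_tables(report, outdir)


def _summary_text(report: RunReport) -> str:
    s = report.correlation_suite
    lines = ["billmech run summary", "====================", ""]
    for (pred, resp), grp in s.groupby(["predictor", "response"], sort=False):
        rho = grp["spearman_rho"].iloc[0]
        p = grp["spearman_p"].iloc[0]
        lines.append(f"{pred} -> {resp}: Spearman rho = {rho:+.3f} (p = {p:.4g})")
        for _, row in grp.iterrows():
            lines.append(
                f"  PGLS {row['lambda_mode']}: slope {row['slope']:+.3e}, "
                f"p = {row['p_value']:.4g}, adj R2 = {row['adjusted_R2']:.3f}, "
                f"lambda = {row['lambda']:.3f}"
            )
    lines.append("")
    lines.append("composite vs homogeneous (median % difference; >0 = composite better):")
    for _, row in report.composite_comparison.iterrows():
        lines.append(
            f"  {row['regime']} x {row['homogeneous_material']}: "
            f"{row['median_pct_difference']:+.2f}% (wilcoxon p = {row['wilcoxon_p']:.4g})"
        )
    return "\n".join(lines) + "\n"


def make_fig_tables(report: RunReport, outdir) -> list[Path]:
    """Emit the figure-style tables: per-species peak VM, the performance-space
    scatter and theory grids, and the paired-difference table."""
    if report.species_results.empty:
        raise ValueError("empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    peak = report.species_results.pivot_table(
        index="species", columns=["regime", "material_mode"], values="peak_vm"
    )
    peak.columns = [f"peak_vm_{r}_{m}" for r, m in peak.columns]
    p1 = outdir / "peak_vm_by_species.csv"
    peak.to_csv(p1)
    written.append(p1)

    scatter = report.comparative_table[["width", "depth", "peak_vm_impact", "peak_vm_torsion"]]
    p2 = outdir / "performance_scatter.csv"
    scatter.to_csv(p2)
    written.append(p2)

    p3 = outdir / "performance_grid.csv"
    report.performance_grid.to_csv(p3, index=False)
    written.append(p3)

    p4 = outdir / "paired_differences.csv"
    report.composite_comparison.to_csv(p4, index=False)
    written.append(p4)
    return written
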