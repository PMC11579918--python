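"""End-to-end synthetic validation study: plant, recover, compare.

``run_validation`` generates three synthetic membrane systems -- a
protein-free bulk reference, a tetramer-like thinned TM window, and a
trimer-like (less thinned) TM window -- each as several independently
seeded replicates, runs the thickness pipeline on each, and reports the
recovered mean +/- SEM against the planted value, together with the
derived relative thinning percentages and the window-thickness difference
between the two protein variants.  Every random stream derives
deterministically from one global seed, so identical configs give
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synthetic import BilayerSpec, generate_bilayer
from .thickness import (
    ThicknessResult,
    relative_thinning,
    thickness_difference,
    thickness_pipeline,
)

__all__ = ["SystemConfig", "RunConfig", "SystemReport", "ValidationReport",
           "run_validation", "replicate_seed"]


@dataclass
class SystemConfig:
    name: str
    planted_thickness: float
    region: str                      # "bulk" | "tm_window"
    bulk_thickness: float = 38.1     # funnel far-field value for window systems


@dataclass
class RunConfig:
    """Resolved parameters of one validation run (serialized verbatim)."""

    systems: list[SystemConfig] = field(
        default_factory=lambda: [
            SystemConfig("bulk", 38.1, "bulk"),
            SystemConfig("wt_window", 20.1, "tm_window"),
            SystemConfig("trimer_window", 23.1, "tm_window"),
        ]
    )
    n_replicates: int = 5
    n_frames: int = 100
    n_lipids_per_leaflet: int = 200
    z_noise_sigma: float = 1.0
    cutoff: float = 6.0
    bin_width: float = 1.0
    protein_radius: float = 10.0
    tolerance: float = 0.5           # |bias| pass/fail threshold, A
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        systems = [SystemConfig(**s) for s in raw.pop("systems", [])]
        cfg = cls(**raw)
        if systems:
            cfg.systems = systems
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SystemReport:
    name: str
    planted: float
    recovered: ThicknessResult
    bias: float
    within_tolerance: bool


@dataclass
class ValidationReport:
    config: RunConfig
    systems: list[SystemReport]
    relative_thinning_pct: dict[str, float]
    window_difference: dict[str, float] | None
    passed: bool

    def to_text(self) -> str:
        lines = ["# memthick synthetic validation report", ""]
        lines.append("system\tplanted_A\trecovered_A\tsem_A\tbias_A\tn_reps\tpass")
        for s in self.systems:
            lines.append(
                f"{s.name}\t{s.planted:.2f}\t{s.recovered.mean:.3f}\t"
                f"{s.recovered.sem:.3f}\t{s.bias:+.3f}\t"
                f"{s.recovered.n_replicates}\t{'yes' if s.within_tolerance else 'NO'}"
            )
        lines.append("")
        for name, pct in self.relative_thinning_pct.items():
            lines.append(f"relative thinning, {name}: {pct:.2f} %")
        if self.window_difference is not None:
            lines.append(
                f"window thickness difference: "
                f"{self.window_difference['difference']:.3f} +/- "
                f"{self.window_difference['propagated_error']:.3f} A"
            )
        lines.append("")
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines) + "\n"


def replicate_seed(global_seed: int, system_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed fan-out from one global seed."""
    ss = np.random.SeedSequence([int(global_seed), int(system_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _system_spec(cfg: RunConfig, sys_cfg: SystemConfig, seed: int) -> BilayerSpec:
    if sys_cfg.region == "bulk":
        return BilayerSpec(
            bulk_thickness=sys_cfg.planted_thickness,
            window_thickness=sys_cfg.planted_thickness,
            protein_radius=0.0,
            n_lipids_per_leaflet=cfg.n_lipids_per_leaflet,
            z_noise_sigma=cfg.z_noise_sigma,
            n_frames=cfg.n_frames,
            seed=seed,
        )
    return BilayerSpec(
        bulk_thickness=sys_cfg.bulk_thickness,
        window_thickness=sys_cfg.planted_thickness,
        protein_radius=cfg.protein_radius,
        window_radius=cfg.protein_radius + cfg.cutoff,
        n_lipids_per_leaflet=cfg.n_lipids_per_leaflet,
        z_noise_sigma=cfg.z_noise_sigma,
        n_frames=cfg.n_frames,
        seed=seed,
    )


def run_validation(config: RunConfig | None = None) -> ValidationReport:
    """Generate, analyze, and score the three-system recovery study."""
    cfg = config or RunConfig()
    reports: list[SystemReport] = []
    results: dict[str, ThicknessResult] = {}
    for si, sys_cfg in enumerate(cfg.systems):
        ensembles = []
        for r in range(cfg.n_replicates):
            spec = _system_spec(cfg, sys_cfg, replicate_seed(cfg.seed, si, r))
            ens, _ = generate_bilayer(spec)
            ensembles.append(ens)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = thickness_pipeline(
                ensembles,
                region=sys_cfg.region,
                cutoff=cfg.cutoff,
                bin_width=cfg.bin_width,
            )
        bias = res.mean - sys_cfg.planted_thickness
        reports.append(
            SystemReport(
                name=sys_cfg.name,
                planted=sys_cfg.planted_thickness,
                recovered=res,
                bias=bias,
                within_tolerance=abs(bias) <= cfg.tolerance,
            )
        )
        results[sys_cfg.name] = res

    thinning: dict[str, float] = {}
    difference = None
    bulk = next((s for s in cfg.systems if s.region == "bulk"), None)
    windows = [s for s in cfg.systems if s.region == "tm_window"]
    if bulk is not None:
        for w in windows:
            thinning[w.name] = relative_thinning(
                results[bulk.name].mean, results[w.name].mean
            )
    if len(windows) >= 2:
        difference = thickness_difference(
            results[windows[1].name], results[windows[0].name]
        )

    report = ValidationReport(
        config=cfg,
        systems=reports,
        relative_thinning_pct=thinning,
        window_difference=difference,
        passed=all(s.within_tolerance for s in reports),
    )
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_report.txt").write_text(report.to_text())
        (out / "resolved_config.json").write_text(
            json.dumps(cfg.to_dict(), indent=2) + "\n"
        )
        with open(out / "per_replicate.tsv", "w") as fh:
            fh.write("system\treplicate\tthickness_A\n")
            for s in report.systems:
                for i, v in enumerate(s.recovered.per_replicate_thickness):
                    fh.write(f"{s.name}\t{i + 1}\t{v:.4f}\n")
    return report
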