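"""End-to-end pipeline: simulate -> qc -> matrices -> varcomp -> predict -> cv -> report.

A single YAML/dict config governs every stage; a :class:`RunManifest`
(config snapshot, seeds, stage wall-clock, output files with SHA-256
digests) is written to the output directory even when a stage fails, so
every output is traceable to config + seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval, kinship, models, plink, qc as qc_mod, reml, simulate

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "matrices", "varcomp", "predict", "cv", "report")

# each stage's direct prerequisites (dependency closure is resolved at run time)
_DEPS = {
    "simulate": (),
    "qc": ("simulate",),
    "matrices": ("qc",),
    "varcomp": ("matrices",),
    "predict": ("varcomp",),
    "cv": ("varcomp",),
    "report": ("cv",),
}


@dataclass
class PipelineConfig:
    """Structured configuration for one run; every default is explicit."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    omega: float = 0.05
    tune_g_to_a22: bool = False
    cv_k: int = 5
    cv_replicates: int = 5
    accuracy_denominator: str = "sqrt_h2"
    export_matrices: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        fx = simulate.FixedEffectSpec(**sim_d.pop("fixed_effect_spec", {}))
        if "founder_freq_range" in sim_d:
            sim_d["founder_freq_range"] = tuple(sim_d["founder_freq_range"])
        qc_d = d.pop("qc", {})
        cfg = cls(
            sim=simulate.SimConfig(fixed_effect_spec=fx, **sim_d),
            qc=qc_mod.QCThresholds(**qc_d),
            **d,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig(**{**self.__dict__})
        cfg.seed = seed
        cfg.sim = simulate.SimConfig(
            **{**simulate.config_to_dict(self.sim), "seed": seed,
               "fixed_effect_spec": self.sim.fixed_effect_spec}
        )
        return cfg

    def snapshot(self) -> dict:
        d = asdict(self)
        d["sim"]["founder_freq_range"] = list(self.sim.founder_freq_range)
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages_run: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    status: str = "incomplete"
    error: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _closure(requested) -> list[str]:
    wanted: set[str] = set()

    def visit(s: str) -> None:
        if s in wanted:
            return
        for dep in _DEPS[s]:
            visit(dep)
        wanted.add(s)

    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
        visit(s)
    return [s for s in STAGES if s in wanted]


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages=STAGES,
) -> RunManifest:
    """Execute the requested stages (plus prerequisites) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), seed=config.seed)
    ctx: dict = {}
    ordered = _closure(stages)

    def record(path: Path) -> None:
        manifest.outputs[str(path)] = _digest(path)

    try:
        for stage in ordered:
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, outdir, ctx, record)
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
            manifest.stages_run.append(stage)
        manifest.status = "ok"
    except Exception as exc:
        manifest.status = "failed"
        manifest.error = (
            f"stage {stage!r}: {exc.__class__.__name__}: {exc}\n"
            + traceback.format_exc(limit=5)
        )
        raise
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    ped, geno_full, phen, truth, geno = simulate.simulate_dataset(cfg.sim)
    ctx.update(ped=ped, geno_full=geno_full, phen=phen, truth=truth, geno_raw=geno)

    ped.write_csv(outdir / "pedigree.csv")
    phen.to_csv(outdir / "phenotypes.csv", index=False)
    truth.write_json(outdir / "truth.json")
    ped_path, map_path = plink.write_ped_map(geno, outdir / "genotypes")
    for p in ("pedigree.csv", "phenotypes.csv", "truth.json"):
        record(outdir / p)
    record(ped_path)
    record(map_path)


def _stage_qc(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    geno_clean, report = qc_mod.apply_qc(ctx["geno_raw"], cfg.qc)
    ctx["geno"] = geno_clean
    ctx["qc_report"] = report
    report.write_csv(outdir / "qc_report.csv")
    ped_path, map_path = plink.write_ped_map(geno_clean, outdir / "genotypes_qc")
    record(outdir / "qc_report.csv")
    record(ped_path)
    record(map_path)


def _stage_matrices(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    ped, geno = ctx["ped"], ctx["geno"]
    a = kinship.numerator_relationship(ped)
    a_inv = kinship.a_inverse(ped)
    a22 = kinship.a22_from_full(a, geno.ids)
    g = kinship.genomic_relationship(geno)
    if cfg.tune_g_to_a22:
        g = kinship.tune_g(g, a22)
    g_blend = kinship.blend_g(g, a22, omega=cfg.omega)
    h_inv = kinship.h_inverse(a_inv, a22, g_blend, geno.ids)
    ctx.update(a=a, a_inv=a_inv, a22=a22, g=g, g_blend=g_blend, h_inv=h_inv)
    if cfg.export_matrices:
        for name, mat in (("A22", a22), ("G_blended", g_blend)):
            path = outdir / f"{name.lower()}_triplets.csv"
            mat.write_triplets(path, tol=1e-12)
            record(path)


def _stage_varcomp(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    phen = ctx["phen"]
    spec = models.ModelSpec()
    vc_a = reml.aireml(phen, spec, ctx["a"])
    ctx["vc_a"] = vc_a

    # pedigree BLUP on the full data -> corrected phenotypes (computed once)
    fit_a = models.solve_mme(phen, spec, ctx["a_inv"], vc_a.sigma_a2, vc_a.sigma_e2)
    ctx["fit_blup"] = fit_a
    yc = models.corrected_phenotypes(fit_a)
    ctx["yc"] = yc
    yc.frame().to_csv(outdir / "corrected_phenotypes.csv", index=False)
    record(outdir / "corrected_phenotypes.csv")

    # single-step AIREML on corrected phenotypes (mean-only model, H matrix);
    # these components drive both genomic prediction methods and Eq-5 h2
    yc_phen = pd.DataFrame({"id": yc.values.index, "trait": yc.values.to_numpy()})
    vc_h = reml.aireml(yc_phen, models.ModelSpec.mean_only(), ctx["h_inv"])
    ctx["vc_h"] = vc_h

    table = pd.DataFrame([
        {"model": "pedigree_A", **vc_a.to_dict()},
        {"model": "ssgblup_H", **vc_h.to_dict()},
    ])
    table.to_csv(outdir / "variance_components.csv", index=False)
    (outdir / "variance_components.json").write_text(
        json.dumps({"pedigree_A": vc_a.to_dict(), "ssgblup_H": vc_h.to_dict()},
                   indent=1, default=str)
    )
    record(outdir / "variance_components.csv")
    record(outdir / "variance_components.json")


def _stage_predict(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    yc, vc_h = ctx["yc"], ctx["vc_h"]
    genotyped = set(ctx["geno"].ids)
    phenotyped = set(yc.values.index)
    rows = []

    fits = {
        "blup": ctx["fit_blup"],
        "gblup": models.gblup(yc, ctx["g_blend"], vc_h.sigma_a2, vc_h.sigma_e2),
        "ssgblup": models.ssgblup(yc, ctx["h_inv"], vc_h.sigma_a2, vc_h.sigma_e2),
    }
    ctx["fits"] = fits
    for method, fit in fits.items():
        for animal, value in fit.breeding_values.items():
            rows.append(
                {
                    "id": animal,
                    "method": method,
                    "trait": "trait",
                    "solution": value,
                    "phenotyped": animal in phenotyped,
                    "genotyped": animal in genotyped,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "breeding_values.csv", index=False)
    record(outdir / "breeding_values.csv")


def _stage_cv(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    yc, vc_h = ctx["yc"], ctx["vc_h"]
    genotyped_with_yc = np.array(
        [a for a in yc.values.index if a in set(ctx["geno"].ids)]
    )
    plans = crossval.make_folds(
        genotyped_with_yc, k=cfg.cv_k, replicates=cfg.cv_replicates, seed=cfg.seed
    )
    data = crossval.CVData(
        yc=yc, g_blend=ctx["g_blend"], h_inv=ctx["h_inv"],
        genotyped_ids=genotyped_with_yc,
    )
    res = {
        m: crossval.run_cv(m, data, plans, vc_h.sigma_a2, vc_h.sigma_e2)
        for m in ("gblup", "ssgblup")
    }
    ctx["cv_results"] = res
    pd.concat([r.folds.assign(method=m) for m, r in res.items()]).to_csv(
        outdir / "cv_folds.csv", index=False
    )
    record(outdir / "cv_folds.csv")


def _stage_report(cfg: PipelineConfig, outdir: Path, ctx: dict, record) -> None:
    res, vc_h = ctx["cv_results"], ctx["vc_h"]
    table = crossval.compare_methods(
        res["gblup"], res["ssgblup"], h2=vc_h.h2,
        denominator=cfg.accuracy_denominator,
    )
    table.to_csv(outdir / "cv_report.csv", index=False)
    record(outdir / "cv_report.csv")
    ctx["report"] = table


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "matrices": _stage_matrices,
    "varcomp": _stage_varcomp,
    "predict": _stage_predict,
    "cv": _stage_cv,
    "report": _stage_report,
}
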