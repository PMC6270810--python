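"""End-to-end orchestration: structures → fields → PLS → reports → maps.

The full workflow mirrors a standard CoMFA study: partial charges,
relaxation (minimize → anneal → minimize), rigid scaffold alignment, grid
field generation, PLS with a LOO component scan, external test-set
validation, and StDev*Coeff contour maps. Every stage is optional and
configurable; every output artifact embeds the configuration hash and seed
so equal hashes imply numerically identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from . import affinity as aff
from .contours import export_dx, stdev_coeff_map
from .fields import FieldMatrix, ProbeSpec, build_field_matrix, make_grid
from .geometry import (
    AnnealConfig,
    MinimizeConfig,
    ScaffoldMap,
    atom_fit,
    minimize,
    simulated_anneal,
)
from .molecules import ChargeConfig, Molecule, gasteiger_charges, read_molecules
from .pls import PLSSummary, field_contributions, final_stats, fit_pls, loo_cv, scan_components
from .synthetic import GeneratorConfig, generate, scaffold_map, scaffold_template, trainsplit

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "validate_tables",
           "ValidationReport", "TABLE1_PRINTED"]

#: printed reference statistics the packaged tables must reproduce
TABLE1_PRINTED = {
    "CB1": {"press": 5.46, "sd": 15.22, "r2_pred": 0.641},
    "CB2": {"press": 2.56, "sd": 10.16, "r2_pred": 0.748},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration tree for one pipeline run.

    Either ``synthetic`` is set (the generator supplies molecules and
    activities) or ``input_sdf``/``activities_csv`` point at user files.
    ``stages`` lists the preprocessing applied before field generation, in
    order; fields/PLS/contours always run.
    """

    synthetic: GeneratorConfig | None = None
    input_sdf: str | None = None
    activities_csv: str | None = None
    template_sdf: str | None = None
    scaffold_map_file: str | None = None
    stages: tuple[str, ...] = ("align",)
    # field settings
    spacing: float = 2.0
    margin: float = 4.0
    cap: float = 30.0
    filter_sigma: float = 2.0
    block_scaling: Literal["inverse_stdev", "none"] = "inverse_stdev"
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    # model settings
    n_components: int | None = None
    scan_max: int = 10
    selection_rule: str = "max_q2"
    fraction_test: float = 0.22
    # contours
    favored_percentile: float = 80.0
    disfavored_percentile: float = 20.0
    # misc
    minimize_cfg: MinimizeConfig = field(default_factory=MinimizeConfig)
    anneal_cfg: AnnealConfig | None = None
    charge_cfg: ChargeConfig = field(default_factory=ChargeConfig)
    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = GeneratorConfig(**data["synthetic"])
        if "probe" in data:
            data["probe"] = ProbeSpec(**data["probe"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    summary: PLSSummary
    predictive: aff.PredictiveStats | None
    predictions: aff.AffinityTable
    alignment_rmsd: list[float]
    n_retained_columns: int
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "model": {
                "n_components": self.summary.n_components,
                "q2": self.summary.q2,
                "sep": self.summary.sep,
                "r2": self.summary.r2,
                "see": self.summary.see,
                "f_stat": self.summary.f_stat,
                "contributions": self.summary.contributions,
                "component_scan": self.summary.component_scan,
            },
            "external_validation": None
            if self.predictive is None
            else dataclasses.asdict(self.predictive),
            "alignment_rmsd_max": max(self.alignment_rmsd, default=0.0),
            "n_retained_columns": self.n_retained_columns,
            "outputs": self.outputs,
        }
        return json.dumps(_as_jsonable(payload), indent=2, sort_keys=True)


def _prepare_structures(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        synth = generate(cfg.synthetic)
        mols = synth.posed if "align" in cfg.stages else [m.copy() for m in synth.molecules]
        table = synth.activities
        template = scaffold_template()
        smap = scaffold_map()
        return mols, table, template, smap
    if not cfg.input_sdf or not cfg.activities_csv:
        raise PipelineError(
            "config needs either synthetic settings or input_sdf + activities_csv"
        )
    from .molecules import assign_vdw_params

    mols = [assign_vdw_params(m) for m in read_molecules(cfg.input_sdf)]
    table = aff.load_csv(cfg.activities_csv)
    template = None
    smap = None
    if "align" in cfg.stages:
        if not cfg.template_sdf or not cfg.scaffold_map_file:
            raise PipelineError(
                "align stage requires template_sdf and scaffold_map_file"
            )
        template = read_molecules(cfg.template_sdf)[0]
        smap = ScaffoldMap.from_file(cfg.scaffold_map_file)
    return mols, table, template, smap


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the configured stages and return (and optionally write) the
    report bundle: model statistics, component scan, per-molecule
    predictions with residuals, and contour maps."""
    mols, table, template, smap = _prepare_structures(cfg)

    stage = "prepare"
    rmsds: list[float] = []
    try:
        for stage in cfg.stages:
            if stage == "charges":
                mols = [gasteiger_charges(m, cfg.charge_cfg) for m in mols]
            elif stage == "minimize":
                mols = [minimize(m, cfg.minimize_cfg)[0] for m in mols]
            elif stage == "anneal":
                base = cfg.anneal_cfg or AnnealConfig(seed=cfg.seed)
                mols = [
                    simulated_anneal(
                        m, dataclasses.replace(base, seed=cfg.seed + k)
                    )
                    for k, m in enumerate(mols)
                ]
            elif stage == "align":
                fitted = []
                for m in mols:
                    f, r = atom_fit(m, template, smap)
                    fitted.append(f)
                    rmsds.append(r)
                mols = fitted
            else:
                raise PipelineError(f"unknown stage {stage!r}")

        stage = "fields"
        grid = make_grid(mols, spacing=cfg.spacing, margin=cfg.margin)
        fm = build_field_matrix(
            mols, grid, probe=cfg.probe, cap=cfg.cap,
            filter_sigma=cfg.filter_sigma, block_scaling=cfg.block_scaling,
        )

        stage = "split"
        if not any(r.split == "test" for r in table.records):
            table = trainsplit(table, cfg.fraction_test, seed=cfg.seed)
        is_train = np.array([r.split == "train" for r in table.records])
        y = np.array([r.pki for r in table.records])
        X = fm.descriptor_matrix()
        if X.shape[0] != y.size:
            raise PipelineError(
                f"{X.shape[0]} structures but {y.size} activity records"
            )

        stage = "pls"
        X_train, y_train = X[is_train], y[is_train]
        scan = None
        if cfg.n_components is None:
            scan, n_comp = scan_components(
                X_train, y_train, n_max=cfg.scan_max, rule=cfg.selection_rule
            )
        else:
            n_comp = cfg.n_components
        model = fit_pls(X_train, y_train, n_comp)
        q2, sep, _ = loo_cv(X_train, y_train, n_comp)
        r2, see, f_stat = final_stats(model, X_train, y_train)
        contributions = field_contributions(model, fm)
        summary = PLSSummary(
            n_components=n_comp, q2=q2, sep=sep, r2=r2, see=see,
            f_stat=f_stat, contributions=contributions, component_scan=scan,
        )

        stage = "predict"
        yhat = model.predict(X)
        pred_table = aff.table_from_predictions(
            table.receptor,
            [r.molecule_id for r in table.records],
            [r.ki_nanomolar for r in table.records],
            y, yhat, [r.split for r in table.records],
        )
        predictive = (
            aff.predictive_stats(pred_table) if pred_table.n_test else None
        )

        stage = "contours"
        maps = {
            name: stdev_coeff_map(
                model, fm, name,
                favored_percentile=cfg.favored_percentile,
                disfavored_percentile=cfg.disfavored_percentile,
            )
            for name in ("steric", "electrostatic")
        }
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = PipelineReport(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        summary=summary,
        predictive=predictive,
        predictions=pred_table,
        alignment_rmsd=rmsds,
        n_retained_columns=fm.n_retained,
    )

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, cmap in maps.items():
            path = outdir / f"{name}.dx"
            export_dx(cmap, path)
            report.outputs[f"{name}_map"] = str(path)
        pred_path = outdir / "predictions.csv"
        pred_table.to_csv(pred_path)
        report.outputs["predictions"] = str(pred_path)
        if scan is not None:
            scan_path = outdir / "component_scan.csv"
            lines = ["n_components,sep,q2"] + [
                f"{n},{s:.6f},{q:.6f}" for n, s, q in scan
            ]
            scan_path.write_text("\n".join(lines) + "\n")
            report.outputs["component_scan"] = str(scan_path)
        report_path = outdir / "report.json"
        report_path.write_text(report.to_json())
        report.outputs["report"] = str(report_path)
    return report


# ---------------------------------------------------------------------------
# fixture validation

@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]]

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def failures(self) -> list[tuple[str, bool, str]]:
        return [c for c in self.checks if not c[1]]

    def __str__(self) -> str:
        lines = []
        for name, passed, detail in self.checks:
            mark = "PASS" if passed else "FAIL"
            lines.append(f"[{mark}] {name}: {detail}")
        lines.append(f"overall: {'PASS' if self.ok else 'FAIL'}")
        return "\n".join(lines)


def validate_tables(tables: dict[str, aff.AffinityTable] | None = None) -> ValidationReport:
    """Recompute every printed statistic from the packaged tables.

    Checks split bookkeeping, per-row pKi/residual consistency, and
    PRESS/SD/r²_pred against the printed reference values at printed
    precision.
    """
    checks: list[tuple[str, bool, str]] = []
    for receptor in aff.RECEPTORS:
        table = tables[receptor] if tables else aff.load_fixture(receptor)
        n_train, n_test = aff.FIXTURE_SPLIT_COUNTS[receptor]
        checks.append(
            (
                f"{receptor} split counts",
                (table.n_train, table.n_test) == (n_train, n_test),
                f"{table.n_train} train / {table.n_test} test "
                f"(expected {n_train}/{n_test})",
            )
        )
        bad_pki = [r.molecule_id for r in table.records if not r.pki_consistent()]
        checks.append(
            (
                f"{receptor} pKi consistency",
                not bad_pki,
                "all rows consistent" if not bad_pki else f"inconsistent: {bad_pki}",
            )
        )
        bad_res = [
            r.molecule_id for r in table.records if not r.residual_consistent()
        ]
        checks.append(
            (
                f"{receptor} residual consistency",
                not bad_res,
                "all rows consistent" if not bad_res else f"inconsistent: {bad_res}",
            )
        )
        stats = aff.predictive_stats(table)
        printed = TABLE1_PRINTED[receptor]
        for key, digits in (("press", 2), ("sd", 2), ("r2_pred", 3)):
            got = round(getattr(stats, key), digits)
            checks.append(
                (
                    f"{receptor} {key}",
                    got == printed[key],
                    f"recomputed {got} vs printed {printed[key]}",
                )
            )
    return ValidationReport(checks=checks)
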