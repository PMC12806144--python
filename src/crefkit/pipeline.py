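"""End-to-end orchestration: build -> decompose -> compare -> enrich -> MPA.

A declarative YAML config names the per-species inputs (a genome+annotation
pair, or a precomputed CREF matrix), the PWM library and threshold profile,
and per-stage settings.  Stages whose inputs are absent are skipped with a
logged warning; every produced file is listed in a run manifest with its
checksum, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .decomposition import DualDecomposition, decompose
from .enrichment import enrich_all, read_gmt
from .matrix import CrefMatrix
from .promoter import build_cref
from .pwm import PwmLibrary, read_pwm_library
from .repeats import mpa_analysis
from .saltation import compare_decompositions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SpeciesInput:
    name: str
    genome: Path | None = None
    gff: Path | None = None
    matrix: Path | None = None


@dataclass
class PipelineConfig:
    species: list[SpeciesInput]
    outdir: Path
    seed: int = 0
    pwms: Path | None = None
    pwm_format: str | None = None
    profile: str = "minFN"
    levels: int = 10
    lam: float | str = "auto"
    tol: float = 1e-7
    max_iter: int = 1000
    reference: str | None = None
    compare_levels: list[int] | None = None
    r_conserved: float = 0.95
    d_small: float = 0.05
    gmt: Path | None = None
    enrich_levels: list[int] | None = None
    enrich_poles: tuple[str, ...] = ("positive",)
    repeats: Path | None = None
    pole_size: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def p(x):
            return None if x is None else (base / x if not Path(x).is_absolute() else Path(x))

        species = [
            SpeciesInput(
                name=s["name"],
                genome=p(s.get("genome")),
                gff=p(s.get("gff")),
                matrix=p(s.get("matrix")),
            )
            for s in raw.get("species", [])
        ]
        dec = raw.get("decomposition", {}) or {}
        cmp_ = raw.get("comparison", {}) or {}
        enr = raw.get("enrichment", {}) or {}
        mpa = raw.get("mpa", {}) or {}
        return cls(
            species=species,
            outdir=p(raw.get("outdir", "cref_out")),
            seed=int(raw.get("seed", 0)),
            pwms=p(raw.get("pwms")),
            pwm_format=raw.get("pwm_format"),
            profile=raw.get("profile", "minFN"),
            levels=int(dec.get("levels", 10)),
            lam=dec.get("lambda", "auto"),
            tol=float(dec.get("tol", 1e-7)),
            max_iter=int(dec.get("max_iter", 1000)),
            reference=cmp_.get("reference"),
            compare_levels=cmp_.get("levels"),
            r_conserved=float(cmp_.get("r_conserved", 0.95)),
            d_small=float(cmp_.get("d_small", 0.05)),
            gmt=p(enr.get("gmt")),
            enrich_levels=enr.get("levels"),
            enrich_poles=tuple(enr.get("poles", ["positive"])),
            repeats=p(mpa.get("repeats")),
            pole_size=int(mpa.get("pole_size", 100)),
        )

    def validate(self) -> None:
        if not self.species:
            raise PipelineError("config", "no species configured")
        for sp in self.species:
            if sp.matrix is None and (sp.genome is None or sp.gff is None):
                raise PipelineError(
                    "config", f"species {sp.name}: need a matrix or genome+gff"
                )
            for path in (sp.genome, sp.gff, sp.matrix):
                if path is not None and not Path(path).exists():
                    raise PipelineError("config", f"missing input file: {path}")
        if any(sp.matrix is None for sp in self.species) and self.pwms is None:
            raise PipelineError("config", "building from sequence requires a PWM library")
        if self.pwms is not None and not Path(self.pwms).exists():
            raise PipelineError("config", f"missing PWM library: {self.pwms}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: dict[str, str] = {}

    def record(label: str, path: Path) -> None:
        outputs[label] = str(path.relative_to(outdir))

    pwm_lib: PwmLibrary | None = None
    if config.pwms is not None:
        pwm_lib = read_pwm_library(config.pwms, config.pwm_format)

    # ---- build ---------------------------------------------------------
    matrices: dict[str, CrefMatrix] = {}
    try:
        for sp in config.species:
            if sp.matrix is not None:
                cref = CrefMatrix.read_tsv(sp.matrix, species=sp.name)
            else:
                cref = build_cref(
                    sp.genome, sp.gff, pwm_lib, config.profile, species=sp.name
                )
            path = outdir / f"{sp.name}.cref.tsv"
            cref.write_tsv(path)
            record(f"cref/{sp.name}", path)
            matrices[sp.name] = cref
        stages["build"] = "ok"
    except Exception as exc:
        raise PipelineError("build", str(exc)) from exc

    # ---- decompose -----------------------------------------------------
    decomps: dict[str, DualDecomposition] = {}
    try:
        for name, cref in matrices.items():
            decomp = decompose(
                cref,
                n_levels=config.levels,
                lam=config.lam,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            for label, path in decomp.write(outdir, prefix=f"{name}.decomp").items():
                record(f"decomp/{name}/{label}", path)
            decomps[name] = decomp
        stages["decompose"] = "ok"
    except Exception as exc:
        raise PipelineError("decompose", str(exc)) from exc

    # ---- stability + comparison ---------------------------------------
    reference = config.reference or config.species[0].name
    if reference not in decomps:
        raise PipelineError("compare", f"reference species {reference!r} not built")
    if len(decomps) >= 2:
        try:
            for name, decomp in decomps.items():
                if name == reference:
                    continue
                result = compare_decompositions(
                    decomps[reference],
                    decomp,
                    levels=config.compare_levels,
                    r_conserved=config.r_conserved,
                    d_small=config.d_small,
                )
                path = outdir / f"compare.{reference}_vs_{name}.tsv"
                result.table.to_csv(path, sep="\t", index=False)
                record(f"compare/{reference}_vs_{name}", path)
            stages["compare"] = "ok"
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc
    else:
        stages["compare"] = "skipped: fewer than two species"
        logger.warning("comparison skipped: fewer than two species")

    # ---- enrichment ----------------------------------------------------
    if config.gmt is not None and Path(config.gmt).exists():
        try:
            collection = read_gmt(config.gmt)
            levels = config.enrich_levels or list(
                range(1, decomps[reference].n_levels + 1)
            )
            table = enrich_all(
                decomps[reference], collection, levels, config.enrich_poles
            )
            path = outdir / f"enrichment.{reference}.tsv"
            table.to_csv(path, sep="\t", index=False)
            record("enrichment", path)
            stages["enrich"] = "ok"
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
    else:
        stages["enrich"] = "skipped: no gene-set collection"
        if config.gmt is not None:
            logger.warning("enrichment skipped: GMT file %s not found", config.gmt)

    # ---- MPA -----------------------------------------------------------
    if (
        config.repeats is not None
        and Path(config.repeats).exists()
        and pwm_lib is not None
    ):
        try:
            result = mpa_analysis(
                decomps,
                pwm_lib,
                config.repeats,
                focal=reference,
                pole_size=config.pole_size,
                profile=config.profile,
            )
            path = outdir / "mpa.tsv"
            result.write_tsv(path)
            record("mpa", path)
            stages["mpa"] = "ok"
        except Exception as exc:
            raise PipelineError("mpa", str(exc)) from exc
    else:
        stages["mpa"] = "skipped: no repeat consensus input"
        if config.repeats is not None and pwm_lib is None:
            logger.warning("MPA skipped: repeats given but no PWM library")

    manifest = {
        "crefkit_version": __version__,
        "seed": config.seed,
        "profile": config.profile,
        "reference": reference,
        "stages": stages,
        "outputs": {
            label: {"path": rel, "sha256": _sha256(outdir / rel)}
            for label, rel in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
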