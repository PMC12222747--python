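"""One-shot orchestration: simulate -> detect -> classify -> distances
-> palette -> assign -> diagram.

A flat YAML config drives the whole run; a single root seed feeds every
stochastic stage through named substreams, so re-running an identical
config reproduces every artifact byte-for-byte.  Each stage writes its
output into the run directory as it completes, and a manifest records
the config hash, seed and the digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .alleles import AllelePanel, FamilyRule, assign_allele
from .catalog import (
    VariantCatalog,
    classify,
    write_architectures_tsv,
)
from .constants import HET_E_CONSENSUS_AA, HYPERVARIABLE_POSITIONS
from .detect import DetectionParams, GeneSequence, detect_repeats, write_track_tsv
from .dissimilarity import distance_matrix, grantham_matrix, load_aa_matrix
from .palette import PaletteConfig, fit_palette
from .simulate import SimulationConfig, simulate_cohort, write_simulation
from .viz import DiagramSpec, write_diagram

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    family_id: str = "het-e"
    consensus_aa: str = HET_E_CONSENSUS_AA
    hypervariable_positions: tuple[int, ...] = HYPERVARIABLE_POSITIONS
    min_repeats: int = 10
    max_repeats: int | None = None
    input_fasta: Path | None = None  # when None, simulate instead
    n_alleles: int = 5
    repeats_range: tuple[int, int] = (6, 12)
    variant_library_size: int = 12
    background_sub_rate: float = 0.0
    flank_length_nt: int = 500
    max_mismatch_nonhv: int = 6
    nt_edit_budget: int = 8
    palette_restarts: int = 4
    palette_iterations: int = 300
    aa_matrix: Path | None = None  # None = packaged Grantham table
    panel: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("out_dir", "input_fasta", "aa_matrix", "panel"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("hypervariable_positions", "repeats_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("input_fasta", "aa_matrix", "panel"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key} does not exist: {path}")

    def config_hash(self) -> str:
        payload = {
            k: str(v) if isinstance(v, Path) else v
            for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class _Run:
    out_dir: Path
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, *paths: Path) -> None:
        for p in paths:
            self.outputs[f"{stage}:{p.name}"] = _digest(p)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Fails fast on config validation; a failure inside a stage raises
    ``PipelineError`` naming the stage, with earlier artifacts left in
    place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(out_dir=out)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrap

    # -- simulate (or load) ------------------------------------------------
    @stage("simulate")
    def genes() -> list[GeneSequence]:
        if config.input_fasta is not None:
            return [
                GeneSequence(id=rec.id, nt=str(rec.seq))
                for rec in SeqIO.parse(str(config.input_fasta), "fasta")
            ]
        sim_cfg = SimulationConfig(
            seed=config.seed,
            consensus_aa=config.consensus_aa,
            hypervariable_positions=config.hypervariable_positions,
            variant_library_size=config.variant_library_size,
            background_sub_rate=config.background_sub_rate,
            flank_length_nt=config.flank_length_nt,
        )
        alleles = simulate_cohort(sim_cfg, config.n_alleles, config.repeats_range)
        fasta, truth = out / "simulated.fasta", out / "truth.tsv"
        write_simulation(alleles, fasta, truth)
        run.record("simulate", fasta, truth)
        return [GeneSequence(id=a.allele_id, nt=a.full_sequence) for a in alleles]

    # -- detect ------------------------------------------------------------
    @stage("detect")
    def tracks():
        params = DetectionParams(
            consensus_aa=config.consensus_aa,
            hypervariable_positions=config.hypervariable_positions,
            max_mismatch_nonhv=config.max_mismatch_nonhv,
            nt_edit_budget=config.nt_edit_budget,
        )
        result = [detect_repeats(g, params) for g in genes]
        track_dir = out / "tracks"
        track_dir.mkdir(exist_ok=True)
        paths = []
        for t in result:
            p = track_dir / f"{t.gene_id}.track.tsv"
            write_track_tsv(t, p)
            paths.append(p)
        run.record("detect", *paths)
        return result

    # -- classify ----------------------------------------------------------
    @stage("classify")
    def classified():
        catalog = VariantCatalog(family_id=config.family_id)
        archs = [
            classify(t, catalog, positions=config.hypervariable_positions)
            for t in tracks
        ]
        cat_path, arch_path = out / "catalog.tsv", out / "architectures.tsv"
        catalog.write_tsv(cat_path)
        write_architectures_tsv(archs, arch_path)
        run.record("classify", cat_path, arch_path)
        return catalog, archs

    catalog, archs = classified

    # -- distances ---------------------------------------------------------
    @stage("distances")
    def dist():
        m = (
            grantham_matrix()
            if config.aa_matrix is None
            else load_aa_matrix(config.aa_matrix)
        )
        D = distance_matrix(catalog, m)
        p = out / "distances.tsv"
        D.to_csv(p, sep="\t")
        run.record("distances", p)
        return D

    # -- palette -----------------------------------------------------------
    @stage("palette")
    def palette():
        cfg = PaletteConfig(
            seed=config.seed,
            n_restarts=config.palette_restarts,
            iterations=config.palette_iterations,
        )
        pal = fit_palette(dist, cfg, family_id=config.family_id)
        p = out / "palette.json"
        pal.write_json(p)
        run.record("palette", p)
        return pal

    # -- assign ------------------------------------------------------------
    @stage("assign")
    def calls_path():
        p = out / "calls.tsv"
        rules = {
            config.family_id: FamilyRule(
                min_repeats=config.min_repeats, max_repeats=config.max_repeats
            )
        }
        with open(p, "w") as fh:
            fh.write("query\texact_match\tphenotype\tnearest\tverdict\n")
            if config.panel is not None:
                panel = AllelePanel.read_tsv(config.panel)
                for arch in archs:
                    call = assign_allele(arch, panel, rules=rules)
                    nearest = ";".join(f"{n}:{d}" for n, d, _ in call.nearest)
                    fh.write(
                        f"{call.query}\t{call.exact_match or '.'}\t"
                        f"{call.phenotype}\t{nearest}\t{call.verdict}\n"
                    )
            else:
                from .alleles import functionality_screen

                for arch in archs:
                    verdict = functionality_screen(arch, rules=rules)
                    fh.write(f"{arch.gene_id}\t.\tunknown\t.\t{verdict}\n")
        run.record("assign", p)
        return p

    # -- diagram -----------------------------------------------------------
    @stage("diagram")
    def diagram_path():
        spec = DiagramSpec(
            rows=[(a.gene_id, a) for a in archs],
            palette=palette,
        )
        p = out / "architectures.svg"
        write_diagram(spec, p)
        run.record("diagram", p)
        return p

    manifest = {
        "tool": "hicrepeats",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": dict(sorted(run.outputs.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
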