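"""Pipeline orchestration: one config document, staged execution, manifest.

Stages run extract -> clonality -> deconvolve, optionally preceded by the
simulator when no input reads are supplied.  All outputs are plain TSV/JSON;
a manifest records package version, resolved parameters, and input checksums
so any stage can be re-run and diffed."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonality import (
    DEFAULT_MIN_CLONE_FRACTION,
    DEFAULT_PRESENCE_THRESHOLD,
    ClonalArchitecture,
    Clone,
    clonal_architecture,
)
from .deconvolve import (
    DEFAULT_AMBIGUITY_MARGIN,
    DEFAULT_REGION_THRESHOLD,
    deconvolve_regions,
)
from .examples import example_pool, papillary_tumor_example
from .extract import extract_reads
from .io import (
    read_region_counts,
    read_whitelist,
    write_cell_truth,
    write_json,
    write_region_truth,
    write_whitelist,
)
from .models import NoiseModel
from .panel import AmpliconPanel, default_panel
from .simulate import simulate_region_bulk, simulate_single_cell_reads, tumor_from_spec

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "inputs", "simulate", "extract", "clonality", "deconvolve"},
    "inputs": {"whitelist", "titers", "panel", "fastq", "regions"},
    "simulate": {"n_cells", "reads_per_region", "tumor", "noise"},
    "simulate.noise": {
        "per_base_error",
        "ambient_fraction",
        "dropout_prob",
        "doublet_rate",
        "reads_per_cell_mean",
        "reads_per_cell_dispersion",
    },
    "simulate.tumor": {"clones", "regions"},
    "extract": {"max_flank_mismatch", "shift_window", "max_hamming"},
    "clonality": {"threshold", "min_clone_fraction", "ends"},
    "deconvolve": {"rel_threshold", "min_margin"},
}


def _check_keys(section: dict, path: str) -> None:
    allowed = _SCHEMA.get(path)
    if allowed is None:
        return
    unknown = set(section) - allowed
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")
    for key, value in section.items():
        if isinstance(value, dict):
            _check_keys(value, f"{path}.{key}" if path else key)


@dataclass
class PipelineConfig:
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    extract: dict = field(default_factory=dict)
    clonality: dict = field(default_factory=dict)
    deconvolve: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, "")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "inputs": self.inputs,
            "simulate": self.simulate,
            "extract": self.extract,
            "clonality": self.clonality,
            "deconvolve": self.deconvolve,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tumor_from_config(spec) -> object:
    if spec in (None, "papillary_example"):
        return papillary_tumor_example()
    if isinstance(spec, dict):
        clones = [
            (c["clone_id"], c["barcodes"], c.get("fitness", 1.0), c.get("histology", "unspecified"))
            for c in spec["clones"]
        ]
        regions = [
            (r["region_id"], r["histology"], r["composition"]) for r in spec["regions"]
        ]
        return tumor_from_spec(clones, regions)
    raise ValueError(f"unrecognised tumour spec {spec!r}")


def architecture_from_frame(df: pd.DataFrame) -> ClonalArchitecture:
    """Rebuild a ClonalArchitecture from a persisted clones.tsv table."""
    clones = [
        Clone(
            clone_id=r["clone_id"],
            barcode_set=frozenset(str(r["barcode_set"]).split(";")),
            n_cells=int(r["n_cells"]),
            frequency=float(r["frequency"]),
            dominant=bool(r["dominant"]),
            doublet_flag=bool(r.get("doublet_flag", False)),
        )
        for r in df.to_dict("records")
    ]
    n_clone_cells = sum(c.n_cells for c in clones)
    freq_sum = sum(c.frequency for c in clones)
    total = round(n_clone_cells / freq_sum) if freq_sum > 0 else n_clone_cells
    assignments = pd.Series(dtype=object, name="clone_id")
    assignments.index.name = "cell_id"
    return ClonalArchitecture(
        clones=clones,
        residual_cells=int(total - n_clone_cells),
        total_cells=int(total),
        cell_assignments=assignments,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured pipeline; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.inputs
    manifest: dict = {"version": __version__, "config": config.to_dict(), "inputs": {}, "outputs": []}

    def _out(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    # --- resolve whitelist and panel
    if inputs.get("whitelist"):
        pool = read_whitelist(inputs["whitelist"], inputs.get("titers"))
        manifest["inputs"]["whitelist"] = _sha256(inputs["whitelist"])
    else:
        pool = example_pool()
        write_whitelist(pool, _out("whitelist.tsv"))
    if inputs.get("panel"):
        panel = AmpliconPanel.from_tsv(inputs["panel"])
        manifest["inputs"]["panel"] = _sha256(inputs["panel"])
    else:
        panel = default_panel()
        panel.to_tsv(_out("panel.tsv"))

    # --- reads: supplied or simulated
    sim = config.simulate
    noise = NoiseModel(**sim.get("noise", {})) if "noise" in sim else NoiseModel()
    if inputs.get("fastq"):
        fastqs = inputs["fastq"]
        if isinstance(fastqs, (str, bytes)):
            fastqs = [fastqs]
        for f in fastqs:
            manifest["inputs"][str(f)] = _sha256(f)
        reads = list(fastqs)
        tumor = None
    else:
        tumor = _tumor_from_config(sim.get("tumor"))
        n_cells = int(sim.get("n_cells", 3000))
        fastq_path = _out("reads.fastq.gz")
        truth, reads = simulate_single_cell_reads(
            tumor, pool, noise, n_cells, panel, seed=config.seed, fastq_path=fastq_path
        )
        write_cell_truth(truth, _out("truth_cells.tsv"))

    # --- region counts: supplied or simulated
    if inputs.get("regions"):
        region_counts = read_region_counts(inputs["regions"])
        manifest["inputs"]["regions"] = _sha256(inputs["regions"])
    elif tumor is not None:
        region_counts, region_truth = simulate_region_bulk(
            tumor, noise, int(sim.get("reads_per_region", 20000)), seed=config.seed
        )
        region_counts.to_csv(_out("region_counts.tsv"), sep="\t", index=False)
        write_region_truth(region_truth, _out("truth_regions.tsv"))
    else:
        region_counts = None

    # --- extract
    ccm = extract_reads(
        reads,
        panel,
        pool,
        max_flank_mismatch=int(config.extract.get("max_flank_mismatch", 2)),
        shift_window=int(config.extract.get("shift_window", 3)),
        max_hamming=int(config.extract.get("max_hamming", 1)),
    )
    ccm.to_tsv(_out("counts5.tsv"), _out("counts3.tsv"), _out("counts.tsv"))
    write_json(ccm.qc, _out("extract_qc.json"))

    # --- clonality
    arch = clonal_architecture(
        ccm,
        threshold=float(config.clonality.get("threshold", DEFAULT_PRESENCE_THRESHOLD)),
        min_cell_fraction=float(
            config.clonality.get("min_clone_fraction", DEFAULT_MIN_CLONE_FRACTION)
        ),
        ends=config.clonality.get("ends", "union"),
    )
    arch.to_frame().to_csv(_out("clones.tsv"), sep="\t", index=False)
    arch.cell_assignments.to_csv(_out("cell_assignments.tsv"), sep="\t")
    write_json(arch.parameters, _out("clonality_params.json"))

    # --- deconvolve
    if region_counts is not None:
        assignments, assoc = deconvolve_regions(
            region_counts,
            arch,
            pool.construct_ids,
            rel_threshold=float(config.deconvolve.get("rel_threshold", DEFAULT_REGION_THRESHOLD)),
            min_margin=float(config.deconvolve.get("min_margin", DEFAULT_AMBIGUITY_MARGIN)),
        )
        assignments.to_csv(_out("region_associations.tsv"), sep="\t", index=False)
        assoc.to_csv(_out("genotype_histology.tsv"), sep="\t", index=False)

    write_json(manifest, outdir / "manifest.json")
    return manifest
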