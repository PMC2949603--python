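"""Readers, writers and run configuration.

On-disk formats: amplicons as FASTA plus a TSV sidecar (0-based half-open
coordinates), curves as wide CSV (temperature column + one column per well)
or long CSV (well/temperature/fluorescence rows) with a JSON metadata sidecar
carrying the stage and the well → sample layout, ground truth and call tables
as TSV with 1-based positions in report output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicons import AmpliconDef, ExonSegment, SequenceVariant
from .calling import ConfirmedVariant, WellCall
from .errors import ConfigError, MeltScanError
from .simulate import (
    GroundTruth,
    GroundTruthRecord,
    MeltCurve,
    MeltModelParams,
    Plate,
    SNPCatalogEntry,
    TillingLibrarySpec,
)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------- amplicons

def _encode_segments(segments) -> str:
    return ";".join(f"{s.start}:{s.end}:{s.frame}" for s in segments) or "."


def _decode_segments(text: str) -> tuple[ExonSegment, ...]:
    text = str(text).strip()
    if text in (".", "", "nan"):
        return ()
    out = []
    for part in text.split(";"):
        start, end, frame = part.split(":")
        out.append(ExonSegment(int(start), int(end), int(frame)))
    return tuple(out)


def write_amplicons(
    amplicons: list[AmpliconDef], fasta_path, annotation_path
) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="") for a in amplicons
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "name": a.name,
            "scanned_start": a.scanned_window[0],
            "scanned_end": a.scanned_window[1],
            "primer_len_left": a.primer_len_left,
            "primer_len_right": a.primer_len_right,
            "exon_segments": _encode_segments(a.exon_segments),
        }
        for a in amplicons
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def read_amplicons(fasta_path, annotation_path) -> list[AmpliconDef]:
    """Load amplicons from FASTA + TSV sidecar, key-matched by record name."""
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    for p in (fasta_path, annotation_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    table = pd.read_csv(annotation_path, sep="\t", dtype={"name": str})
    out = []
    for rec in table.itertuples():
        if rec.name not in sequences:
            raise MeltScanError(
                f"annotation row {rec.name!r} has no FASTA record in {fasta_path}"
            )
        out.append(
            AmpliconDef(
                name=rec.name,
                sequence=sequences[rec.name],
                scanned_window=(int(rec.scanned_start), int(rec.scanned_end)),
                exon_segments=_decode_segments(rec.exon_segments),
                primer_len_left=int(rec.primer_len_left),
                primer_len_right=int(rec.primer_len_right),
            )
        )
    return out


# ------------------------------------------------------------------- curves

def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_curves(
    path, curves: list[MeltCurve], layout: dict[str, str] | None = None,
    dialect: str = "wide",
) -> None:
    """Write curves as wide or long CSV plus a JSON metadata sidecar."""
    path = Path(path)
    if not curves:
        raise MeltScanError("no curves to write")
    stage = curves[0].stage
    if any(c.stage != stage for c in curves):
        raise MeltScanError("all curves in one file must share a stage")
    if dialect == "wide":
        grid = curves[0].temperatures
        for c in curves[1:]:
            if not np.array_equal(c.temperatures, grid):
                raise MeltScanError("wide dialect needs a shared temperature grid")
        df = pd.DataFrame({"temperature": grid})
        for c in curves:
            df[c.well_id] = c.values
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "well_id": c.well_id,
                    "temperature": c.temperatures,
                    "fluorescence": c.values,
                }
            )
            for c in curves
        ]
        df = pd.concat(frames, ignore_index=True)
    else:
        raise MeltScanError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "stage": stage,
        "samples": {c.well_id: c.sample_id for c in curves},
        "layout": layout or {},
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_curves(path) -> list[MeltCurve]:
    """Read a curve CSV, auto-detecting the wide vs long dialect by header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing curves file: {path}")
    meta_file = _meta_path(path)
    meta = (
        json.loads(meta_file.read_text())
        if meta_file.exists()
        else {"stage": "raw", "samples": {}}
    )
    stage = meta.get("stage", "raw")
    samples = meta.get("samples", {})
    df = pd.read_csv(path)
    curves = []
    if set(df.columns) >= {"well_id", "temperature", "fluorescence"}:
        for well, grp in df.groupby("well_id", sort=False):
            curves.append(
                MeltCurve(
                    well_id=str(well),
                    sample_id=samples.get(str(well), str(well)),
                    stage=stage,
                    temperatures=grp["temperature"].to_numpy(),
                    values=grp["fluorescence"].to_numpy(),
                )
            )
    elif df.columns[0] == "temperature":
        t = df["temperature"].to_numpy()
        for col in df.columns[1:]:
            curves.append(
                MeltCurve(
                    well_id=str(col),
                    sample_id=samples.get(str(col), str(col)),
                    stage=stage,
                    temperatures=t,
                    values=df[col].to_numpy(),
                )
            )
    else:
        raise MeltScanError(
            f"{path}: header matches neither the wide nor the long dialect"
        )
    return curves


def write_plates(out_dir, plates: list[Plate]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for plate in plates:
        write_curves(
            out_dir / f"{plate.plate_id}.csv", plate.curves, layout=plate.layout
        )


def read_plates(out_dir) -> list[Plate]:
    out_dir = Path(out_dir)
    plates = []
    for path in sorted(out_dir.glob("*.csv")):
        curves = read_curves(path)
        meta = json.loads(_meta_path(path).read_text())
        plate_id = path.stem
        amplicon = plate_id.rsplit("-P", 1)[0]
        plates.append(Plate(plate_id, amplicon, curves, meta.get("layout", {})))
    return plates


# ------------------------------------------------------------- ground truth

def write_ground_truth(path, truth: GroundTruth) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "amplicon": r.amplicon,
            "position": r.variant.position + 1,  # 1-based in reports
            "change": f"{r.variant.ref_base}>{r.variant.alt_base}",
            "origin": r.variant.origin,
            "zygosity": r.variant.zygosity,
            "distance_to_end": r.distance_to_end,
        }
        for r in truth.records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "amplicon", "position", "change", "origin",
            "zygosity", "distance_to_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing ground-truth file: {path}")
    df = pd.read_csv(path, sep="\t")
    truth = GroundTruth()
    for rec in df.itertuples():
        ref, alt = str(rec.change).split(">")
        truth.records.append(
            GroundTruthRecord(
                sample_id=str(rec.sample_id),
                amplicon=str(rec.amplicon),
                variant=SequenceVariant(
                    position=int(rec.position) - 1,
                    ref_base=ref,
                    alt_base=alt,
                    origin=str(rec.origin),
                    zygosity=str(rec.zygosity),
                ),
                distance_to_end=int(rec.distance_to_end),
            )
        )
    return truth


# -------------------------------------------------------------- call tables

def calls_to_frame(calls: list[WellCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": c.well_id,
                "sample_id": c.sample_id,
                "plate_id": c.plate_id,
                "step": c.step,
                "metric_max_abs": round(c.metric_max_abs, 6),
                "metric_signed_area": round(c.metric_signed_area, 6),
                "threshold": round(c.threshold, 6),
                "label": c.label,
            }
            for c in calls
        ]
    )


def confirmed_to_frame(confirmed: list[ConfirmedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": cv.sample_id,
                "amplicon": cv.amplicon,
                "position": cv.variant.position + 1,
                "change": f"{cv.variant.ref_base}>{cv.variant.alt_base}",
                "origin": cv.variant.origin,
                "zygosity": cv.variant.zygosity,
                "plate_id": cv.plate_id,
                "occurrence_count": cv.occurrence_count,
                "classification": cv.classification or "",
            }
            for cv in confirmed
        ],
        columns=[
            "sample_id", "amplicon", "position", "change", "origin",
            "zygosity", "plate_id", "occurrence_count", "classification",
        ],
    )


def write_vcf(path, confirmed: list[ConfirmedVariant], amplicons) -> None:
    """Minimal VCF-style export of confirmed variants (CHROM = amplicon)."""
    amp_by_name = {a.name: a for a in amplicons}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="mutation or snp">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="library sample">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for name, a in amp_by_name.items():
        lines.insert(1, f"##contig=<ID={name},length={len(a.sequence)}>")
    for cv in confirmed:
        v = cv.variant
        info = f"CLASS={cv.classification or 'unclassified'};SAMPLE={cv.sample_id}"
        lines.append(
            f"{cv.amplicon}\t{v.position + 1}\t.\t{v.ref_base}\t{v.alt_base}"
            f"\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -------------------------------------------------------------------- config

@dataclass(frozen=True)
class CallerConfig:
    sensitivity: str = "high"
    abs_floor: float = 0.5
    snp_scope: str = "global"
    snp_min_count: int = 3
    overlay_threshold_pct: float = 10.0


@dataclass(frozen=True)
class LibraryConfig:
    n_samples: int = 96
    mutation_rate_per_bp: float = 1.0 / 314206.0
    plate_size: int = 96
    substitution_spectrum: str = "uniform"
    snps: tuple = ()  # (amplicon, position(1-based), ref, alt, allele_frequency)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    amplicon_fasta: str
    amplicon_tsv: str
    out_dir: str = "meltscan_out"
    seed: int = 0
    genome_size_bp: int | None = None
    params: MeltModelParams = field(default_factory=MeltModelParams)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)


def _strict_build(cls, mapping, where):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    return mapping


def config_from_dict(data: dict) -> RunConfig:
    data = dict(_strict_build(RunConfig, data, "config"))
    if "params" in data:
        data["params"] = MeltModelParams(
            **_strict_build(MeltModelParams, data["params"], "config.params")
        )
    if "library" in data:
        lib = dict(_strict_build(LibraryConfig, data["library"], "config.library"))
        if "snps" in lib:
            lib["snps"] = tuple(tuple(s) for s in lib["snps"])
        data["library"] = LibraryConfig(**lib)
    if "caller" in data:
        data["caller"] = CallerConfig(
            **_strict_build(CallerConfig, data["caller"], "config.caller")
        )
    for key in ("amplicon_fasta", "amplicon_tsv"):
        if key not in data:
            raise ConfigError(f"config: missing required key {key!r}")
    return RunConfig(**data)


def config_to_dict(config: RunConfig) -> dict:
    data = dataclasses.asdict(config)
    data["library"]["snps"] = [list(s) for s in config.library.snps]
    return data


def read_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def write_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def library_spec_from_config(config: RunConfig, amplicons) -> TillingLibrarySpec:
    snp_catalog = []
    for amp_name, pos, ref, alt, freq in config.library.snps:
        snp_catalog.append(
            (
                str(amp_name),
                SNPCatalogEntry(
                    SequenceVariant(int(pos) - 1, str(ref), str(alt), origin="snp"),
                    float(freq),
                ),
            )
        )
    return TillingLibrarySpec(
        n_samples=config.library.n_samples,
        amplicons=tuple(amplicons),
        mutation_rate_per_bp=config.library.mutation_rate_per_bp,
        snp_catalog=tuple(snp_catalog),
        plate_size=config.library.plate_size,
        substitution_spectrum=config.library.substitution_spectrum,
    )
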