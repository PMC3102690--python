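"""Reading and writing PBM samples, probe designs, models and predictions.

All formats are plain tab-separated text.  A sample table has the header
``probe_id  row  col  sequence  intensity`` with 1-based grid coordinates
(microarray convention) and the literal ``NA`` for missing intensities;
optional ``#key=value`` lines before the header carry processing metadata
so that a preprocessed sample round-trips losslessly.  Probe designs may
alternatively be given as FASTA (record id = probe id) paired with a
coordinate TSV.  Affinity-model files hold a ``#key=value`` header block
followed by a (pattern, gap_offset, alpha) table and carry a format
version tag.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (GridIntegrityError, ModelFormatError,
                         SampleParseError, SequenceAlphabetError)
from .kmers import KmerFeature, KmerSet
from .model import AffinityModel, NoiseModel

MODEL_FORMAT_VERSION = 1
SAMPLE_COLUMNS = ["probe_id", "row", "col", "sequence", "intensity"]
_FLOAT_FMT = "%.17g"


@dataclass
class ProbeRecord:
    """One microarray spot: id, 1-based grid position, full sequence
    (flank + interrogating region) and raw or processed intensity
    (None when missing/discarded)."""

    probe_id: str
    grid_row: int
    grid_col: int
    sequence: str
    intensity: float | None


@dataclass
class PBMSample:
    """One hybridization: a probe table plus processing metadata.

    ``probes`` is a DataFrame with columns probe_id, row, col, sequence,
    intensity (NaN = missing).  ``provenance`` is the append-only list of
    processing steps already applied.
    """

    probes: pd.DataFrame
    grid_shape: tuple[int, int]
    log_base: float | None = None
    subtracted_mean: float | None = None
    provenance: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        lengths = self.probes["sequence"].str.len().unique()
        if len(lengths) > 1:
            raise SampleParseError(
                f"probe sequences have unequal lengths: {sorted(lengths)}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def sequence_length(self) -> int:
        return len(self.probes["sequence"].iloc[0]) if self.n_probes else 0

    def sequences(self) -> list[str]:
        return list(self.probes["sequence"])

    def intensities(self) -> np.ndarray:
        """Intensity vector in probe order, NaN for missing."""
        return self.probes["intensity"].to_numpy(dtype=float)

    def set_intensities(self, values: np.ndarray) -> None:
        self.probes["intensity"] = np.asarray(values, dtype=float)

    def records(self) -> list[ProbeRecord]:
        out = []
        for t in self.probes.itertuples(index=False):
            inten = None if math.isnan(t.intensity) else float(t.intensity)
            out.append(ProbeRecord(t.probe_id, int(t.row), int(t.col),
                                   t.sequence, inten))
        return out

    def copy(self) -> "PBMSample":
        return PBMSample(self.probes.copy(), self.grid_shape, self.log_base,
                         self.subtracted_mean, list(self.provenance),
                         self.name)

    def grid(self) -> np.ndarray:
        """Intensities arranged on the (rows, cols) grid, NaN elsewhere."""
        g = np.full(self.grid_shape, np.nan)
        r = self.probes["row"].to_numpy() - 1
        c = self.probes["col"].to_numpy() - 1
        g[r, c] = self.intensities()
        return g

    def set_from_grid(self, grid: np.ndarray) -> None:
        r = self.probes["row"].to_numpy() - 1
        c = self.probes["col"].to_numpy() - 1
        self.probes["intensity"] = grid[r, c]


def _read_meta_lines(path) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body_lines = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") and not body_lines:
                line = line[1:].strip()
                if "=" in line:
                    key, _, value = line.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _validate_probe_table(df: pd.DataFrame, n_meta: int, path) -> pd.DataFrame:
    def lineno(idx: int) -> int:
        return n_meta + 2 + idx  # header line + 1-based

    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SampleParseError(
            f"{path}: missing required columns {missing_cols}")
    df = df[SAMPLE_COLUMNS].copy()
    for col in ("probe_id", "row", "col", "sequence"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SampleParseError(
                f"{path}: line {lineno(bad[0])}: empty {col} field")
    try:
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SampleParseError(f"{path}: non-integer grid coordinate: {exc}")
    if (df["row"] < 1).any() or (df["col"] < 1).any():
        bad = df.index[(df["row"] < 1) | (df["col"] < 1)][0]
        raise GridIntegrityError(
            f"{path}: line {lineno(bad)}: grid coordinates are 1-based")
    dup = df.duplicated(subset=["row", "col"])
    if dup.any():
        bad = df.index[dup][0]
        raise GridIntegrityError(
            f"{path}: line {lineno(bad)}: duplicate grid position "
            f"({df.loc[bad, 'row']}, {df.loc[bad, 'col']})")
    df["sequence"] = df["sequence"].astype(str).str.upper()
    ok = df["sequence"].str.fullmatch("[ACGT]+")
    if not ok.all():
        bad = df.index[~ok][0]
        raise SequenceAlphabetError(
            f"{path}: line {lineno(bad)}: sequence contains non-ACGT "
            f"characters: {df.loc[bad, 'sequence']}")
    inten = pd.to_numeric(df["intensity"], errors="coerce")
    unparsed = df["intensity"].notna() & inten.isna()
    if unparsed.any():
        bad = df.index[unparsed][0]
        raise SampleParseError(
            f"{path}: line {lineno(bad)}: non-numeric intensity "
            f"{df.loc[bad, 'intensity']!r}")
    df["intensity"] = inten
    raw = df["intensity"]
    if ((raw < 0) & raw.notna()).any():
        bad = df.index[(raw < 0) & raw.notna()][0]
        raise SampleParseError(
            f"{path}: line {lineno(bad)}: negative intensity")
    return df


def read_sample(path, format: str = "tsv", fasta=None) -> PBMSample:
    """Read a PBM sample table.

    ``format='tsv'``: single table with the standard five columns.
    ``format='fasta+tsv'``: ``fasta`` holds the probe sequences (record id
    = probe_id) and ``path`` the coordinate table (probe_id, row, col and
    optionally intensity).
    """
    if format == "fasta+tsv":
        if fasta is None:
            raise ValueError("fasta path required for format='fasta+tsv'")
        meta, body = _read_meta_lines(path)
        coords = pd.read_csv(_io.StringIO(body), sep="\t", dtype={"probe_id": str},
                             na_values=["NA"], keep_default_na=False)
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta), "fasta")}
        missing = [p for p in coords["probe_id"] if p not in seqs]
        if missing:
            raise SampleParseError(
                f"{path}: probe ids missing from FASTA: {missing[:5]}")
        coords["sequence"] = [seqs[p] for p in coords["probe_id"]]
        if "intensity" not in coords.columns:
            coords["intensity"] = np.nan
        df = _validate_probe_table(coords, len(meta), path)
    elif format == "tsv":
        meta, body = _read_meta_lines(path)
        try:
            df = pd.read_csv(_io.StringIO(body), sep="\t",
                             dtype={"probe_id": str, "sequence": str},
                             na_values=["NA"], keep_default_na=False,
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise SampleParseError(f"{path}: malformed table: {exc}")
        df = _validate_probe_table(df, len(meta), path)
    else:
        raise ValueError(f"unknown sample format {format!r}")

    grid_shape = (int(df["row"].max()), int(df["col"].max()))
    if "grid_shape" in meta:
        r, c = meta["grid_shape"].split(",")
        grid_shape = (int(r), int(c))
    provenance = ([s for s in meta["provenance"].split(",") if s]
                  if "provenance" in meta else [])
    return PBMSample(
        probes=df,
        grid_shape=grid_shape,
        log_base=float(meta["log_base"]) if "log_base" in meta else None,
        subtracted_mean=(float(meta["subtracted_mean"])
                         if "subtracted_mean" in meta else None),
        provenance=provenance,
        name=meta.get("name", ""),
    )


def write_sample(sample: PBMSample, path) -> None:
    with open(path, "wt") as fh:
        if sample.name:
            fh.write(f"#name={sample.name}\n")
        fh.write(f"#grid_shape={sample.grid_shape[0]},{sample.grid_shape[1]}\n")
        if sample.log_base is not None:
            fh.write("#log_base=" + _FLOAT_FMT % sample.log_base + "\n")
        if sample.subtracted_mean is not None:
            fh.write("#subtracted_mean=" + _FLOAT_FMT % sample.subtracted_mean
                     + "\n")
        if sample.provenance:
            fh.write("#provenance=" + ",".join(sample.provenance) + "\n")
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for t in sample.probes.itertuples(index=False):
            inten = "NA" if math.isnan(t.intensity) else _FLOAT_FMT % t.intensity
            fh.write(f"{t.probe_id}\t{t.row}\t{t.col}\t{t.sequence}\t{inten}\n")


def read_design(path, format: str = "tsv") -> list[tuple[str, str]]:
    """Read a probe design as (probe_id, sequence) pairs.

    Accepts a full sample TSV, a two-column (probe_id, sequence) TSV, or a
    FASTA file.
    """
    if format == "fasta":
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
    meta, body = _read_meta_lines(path)
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str,
                     na_values=["NA"], keep_default_na=False)
    if "probe_id" not in df.columns or "sequence" not in df.columns:
        raise SampleParseError(
            f"{path}: design table needs probe_id and sequence columns")
    seqs = df["sequence"].str.upper()
    bad = ~seqs.str.fullmatch("[ACGT]+")
    if bad.any():
        raise SequenceAlphabetError(
            f"{path}: non-ACGT design sequence for probe "
            f"{df['probe_id'][bad.idxmax()]}")
    return list(zip(df["probe_id"], seqs))


def write_model(model: AffinityModel, path) -> None:
    """Serialize a fitted affinity model (>= 17 significant digits)."""
    with open(path, "wt") as fh:
        fh.write(f"#version={MODEL_FORMAT_VERSION}\n")
        if model.log_base is not None:
            fh.write("#log_base=" + _FLOAT_FMT % model.log_base + "\n")
        fh.write("#training_mean=" + _FLOAT_FMT % model.training_mean + "\n")
        fh.write("#intercept=" + _FLOAT_FMT % model.intercept + "\n")
        fh.write(f"#cg_iterations={model.cg_iterations}\n")
        fh.write(f"#variant={model.variant}\n")
        fh.write(f"#strand_tied={int(model.kmer_set.strand_tied)}\n")
        if model.training_probe_length is not None:
            fh.write(f"#training_probe_length={model.training_probe_length}\n")
        fh.write("pattern\tgap_offset\talpha\n")
        for f, a in zip(model.kmer_set.features, model.alpha):
            g = "NA" if f.gap_offset is None else str(f.gap_offset)
            fh.write(f"{f.pattern}\t{g}\t" + _FLOAT_FMT % a + "\n")


def read_model(path) -> AffinityModel:
    meta, body = _read_meta_lines(path)
    if meta.get("version") != str(MODEL_FORMAT_VERSION):
        raise ModelFormatError(
            f"{path}: unsupported model format version "
            f"{meta.get('version')!r} (expected {MODEL_FORMAT_VERSION})")
    for key in ("training_mean", "intercept"):
        if key not in meta:
            raise ModelFormatError(f"{path}: missing header key {key}")
    df = pd.read_csv(_io.StringIO(body), sep="\t",
                     dtype={"pattern": str, "gap_offset": str},
                     na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    strand_tied = bool(int(meta.get("strand_tied", "0")))
    features = []
    for t in df.itertuples(index=False):
        g = None if pd.isna(t.gap_offset) or t.gap_offset == "" \
            else int(t.gap_offset)
        features.append(KmerFeature(t.pattern, g, canonical=strand_tied))
    kmer_set = KmerSet(features, strand_tied=strand_tied)
    alpha = df["alpha"].to_numpy(dtype=float) if len(df) else np.zeros(0)
    return AffinityModel(
        kmer_set=kmer_set,
        alpha=alpha,
        intercept=float(meta["intercept"]),
        training_mean=float(meta["training_mean"]),
        cg_iterations=int(meta.get("cg_iterations", "10")),
        variant=meta.get("variant", "joint"),
        log_base=float(meta["log_base"]) if "log_base" in meta else None,
        training_probe_length=(int(meta["training_probe_length"])
                               if "training_probe_length" in meta else None),
    )


def write_kmer_set(kmer_set: KmerSet, path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"#strand_tied={int(kmer_set.strand_tied)}\n")
        fh.write("pattern\tk\tgap_offset\tcanonical\n")
        for f in kmer_set.features:
            g = "NA" if f.gap_offset is None else str(f.gap_offset)
            fh.write(f"{f.pattern}\t{f.k}\t{g}\t{int(f.canonical)}\n")


def read_kmer_set(path) -> KmerSet:
    meta, body = _read_meta_lines(path)
    df = pd.read_csv(_io.StringIO(body), sep="\t",
                     dtype={"pattern": str, "gap_offset": str},
                     na_values=["NA"], keep_default_na=False)
    features = []
    for t in df.itertuples(index=False):
        g = None if pd.isna(t.gap_offset) or t.gap_offset == "" \
            else int(t.gap_offset)
        features.append(KmerFeature(t.pattern, g, bool(int(t.canonical))))
    return KmerSet(features, strand_tied=bool(int(meta.get("strand_tied", "0"))))


def write_predictions(probe_ids, predicted_intensities, path) -> None:
    """Two-column TSV (probe_id, predicted_intensity), order preserved."""
    ids = list(probe_ids)
    vals = list(predicted_intensities)
    if len(ids) != len(vals):
        raise ValueError(
            f"{len(ids)} probe ids but {len(vals)} predicted values")
    with open(path, "wt") as fh:
        fh.write("probe_id\tpredicted_intensity\n")
        for pid, v in zip(ids, vals):
            fh.write(f"{pid}\t" + _FLOAT_FMT % v + "\n")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str})


def write_noise_model(nm: NoiseModel, path) -> None:
    with open(path, "wt") as fh:
        fh.write("sigma0\t" + _FLOAT_FMT % nm.sigma0 + "\n")
        fh.write("beta\t" + _FLOAT_FMT % nm.beta + "\n")
        if nm.source_replicates:
            fh.write("replicates\t" + ",".join(nm.source_replicates) + "\n")


def read_noise_model(path) -> NoiseModel:
    vals: dict[str, str] = {}
    with open(path, "rt") as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            vals[key] = value
    reps = vals.get("replicates", "")
    return NoiseModel(float(vals["sigma0"]), float(vals["beta"]),
                      reps.split(",") if reps else [])
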