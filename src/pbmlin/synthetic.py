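"""Synthetic two-platform PBM experiments with planted affinity structure.

The generator mirrors the model's own data-generating assumptions: each
probe is a shared 25-base flank plus a random 36-base interrogating
sequence laid out on a near-square grid, and its clean log2 intensity is a
background mean plus the summed affinities of the planted K-mers it
contains (forward strand).  Optional artifacts emulate what real arrays
suffer: intensity-dependent Gaussian noise, a multiplicative spatial
blotch, and clamping of the bright tail at a saturation ceiling with an
infinitesimal rank-preserving jitter (real saturated probes retain an
ordering just below the ceiling).

Two platforms share the planted affinities but use distinct probe designs
and flanks, emulating cross-platform training/prediction experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .io import PBMSample
from .kmers import ALPHABET, KmerFeature, _window_patterns
from .model import AffinityModel

# 25-base flanks, one per platform (probe-invariant primer regions)
DEFAULT_FLANK_A = "GTCTTGATTCGCTTGACGCTGCTGA"
DEFAULT_FLANK_B = "CTAGGATCCGAATTCGCCCTATAGT"


@dataclass
class NoiseSpec:
    """Probe noise: none, constant-sd Gaussian, or affine intensity-
    proportional sd sigma(mu) = sigma0 + beta * mu (log scale)."""

    kind: str = "none"  # none | gaussian | linear
    sd: float = 0.0
    sigma0: float = 0.0
    beta: float = 0.0

    def sigmas(self, clean_log: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(clean_log)
        if self.kind == "gaussian":
            return np.full_like(clean_log, self.sd)
        if self.kind == "linear":
            return np.maximum(self.sigma0 + self.beta * clean_log, 0.0)
        raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class BlotchSpec:
    """Multiplicative spatial artifact: log intensities of spots within
    ``radius`` of (center_row, center_col) are multiplied by ``multiplier``."""

    center_row: int
    center_col: int
    radius: float
    multiplier: float


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-platform experiment."""

    n_probes_a: int = 5000
    n_probes_b: int = 5000
    probe_length: int = 36
    flank_a: str = DEFAULT_FLANK_A
    flank_b: str = DEFAULT_FLANK_B
    planted: list[tuple[KmerFeature, float]] = field(default_factory=list)
    background_mean: float = 8.0
    log_base: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    saturation_quantile: float = 1.0
    blotch: BlotchSpec | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh) or {}
        planted = [
            (KmerFeature(d["pattern"], d.get("gap_offset")), float(d["affinity"]))
            for d in raw.pop("planted", [])
        ]
        noise = NoiseSpec(**raw.pop("noise", {}))
        blotch = raw.pop("blotch", None)
        if blotch is not None:
            blotch = BlotchSpec(**blotch)
        cfg = cls(planted=planted, noise=noise, blotch=blotch, **raw)
        return cfg


# Affinity ranges (log2 units) per K-mer length.  Binding energy is roughly
# additive per matched position, so longer matches to the core motif bind
# strongest while short K-mers contribute weak context preferences.
DEFAULT_AFFINITY_RANGES = {
    4: (0.1, 0.4), 5: (0.2, 0.6), 6: (0.5, 1.0), 7: (1.0, 2.0), 8: (1.5, 3.0),
}


def default_planted_features(seed: int = 0, n: int = 20,
                             lengths: tuple[int, ...] = (4, 5, 6),
                             affinity_ranges: dict | None = None,
                             forbidden_contexts: tuple[str, ...] = (
                                 DEFAULT_FLANK_A, DEFAULT_FLANK_B),
                             ) -> list[tuple[KmerFeature, float]]:
    """Random planted binding profile: n distinct K-mers cycling through
    ``lengths`` with positive affinities (binding raises fluorescence)
    drawn uniformly from a length-dependent range in log2 units.

    Patterns occurring inside a ``forbidden_contexts`` string (the shared
    flanks) are rejected: a motif inside the probe-invariant flank appears
    in every probe, is confounded with the constant background, and is
    unrecoverable by any method.

    The default lengths 4-6 reflect motif core widths whose K-mer space a
    few-thousand-probe random design actually covers (each 6-mer occurs in
    ~70 of 5000 probes, an 8-mer in only ~4); longer-motif experiments
    pass ``lengths=(8,)`` etc. together with correspondingly larger
    designs.
    """
    ranges = affinity_ranges or DEFAULT_AFFINITY_RANGES
    rng = np.random.default_rng(seed)
    planted: list[tuple[KmerFeature, float]] = []
    seen: set[str] = set()
    i = 0
    while len(planted) < n:
        k = lengths[i % len(lengths)]
        pat = "".join(rng.choice(list(ALPHABET), size=k))
        if pat in seen or any(pat in ctx for ctx in forbidden_contexts):
            continue
        seen.add(pat)
        aff = float(rng.uniform(*ranges[k]))
        planted.append((KmerFeature(pat), aff))
        i += 1
    return planted


def _grid_layout(n: int) -> tuple[int, int]:
    rows = math.ceil(math.sqrt(n))
    cols = math.ceil(n / rows)
    return rows, cols


def simulate_design(n_probes: int, probe_length: int = 36,
                    flank: str = DEFAULT_FLANK_A, seed: int = 0,
                    prefix: str = "probe") -> PBMSample:
    """Random probe design: i.i.d. uniform interrogating sequences prefixed
    by the shared flank, laid out row-major on a near-square grid.  The
    returned sample has missing intensities."""
    rng = np.random.default_rng(seed)
    bases = np.array(list(ALPHABET))
    idx = rng.integers(0, 4, size=(n_probes, probe_length))
    seqs = [flank + "".join(bases[row]) for row in idx]
    rows_n, cols_n = _grid_layout(n_probes)
    r = np.arange(n_probes) // cols_n + 1
    c = np.arange(n_probes) % cols_n + 1
    probes = pd.DataFrame({
        "probe_id": [f"{prefix}_{i:05d}" for i in range(n_probes)],
        "row": r, "col": c, "sequence": seqs,
        "intensity": np.nan,
    })
    return PBMSample(probes, grid_shape=(rows_n, cols_n), name=prefix)


def planted_log_intensities(sequences: list[str],
                            planted: list[tuple[KmerFeature, float]],
                            background_mean: float) -> np.ndarray:
    """Clean log intensity of each sequence under the planted linear model
    (background plus the affinity of every planted K-mer it contains)."""
    out = np.full(len(sequences), float(background_mean))
    for f, aff in planted:
        if f.gap_offset is None:
            hits = np.fromiter((f.pattern in s for s in sequences),
                               dtype=bool, count=len(sequences))
        else:
            hits = np.fromiter(
                (any(p == f.pattern
                     for p in _window_patterns(s, f.k, f.gap_offset))
                 for s in sequences), dtype=bool, count=len(sequences))
        out[hits] += aff
    return out


def simulate_intensities(design: PBMSample, config: SimulationConfig,
                         seed: int | None = None) -> PBMSample:
    """Raw intensities for a design: base ** (clean log + noise), then the
    optional blotch and saturation clamp.  Deterministic under seed."""
    if not 0.0 < config.saturation_quantile <= 1.0:
        raise ValueError("saturation_quantile must be in (0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    seqs = design.sequences()
    log_clean = planted_log_intensities(seqs, config.planted,
                                        config.background_mean)
    sig = config.noise.sigmas(log_clean)
    log_v = log_clean + rng.standard_normal(len(seqs)) * sig

    out = design.copy()
    out.set_intensities(log_v)
    if config.blotch is not None:
        b = config.blotch
        grid = out.grid()
        rr, cc = np.mgrid[0:grid.shape[0], 0:grid.shape[1]]
        inside = ((rr - (b.center_row - 1)) ** 2
                  + (cc - (b.center_col - 1)) ** 2) <= b.radius ** 2
        grid[inside] *= b.multiplier
        out.set_from_grid(grid)

    raw = config.log_base ** out.intensities()
    if config.saturation_quantile < 1.0:
        ceiling = float(np.quantile(raw, config.saturation_quantile))
        over = raw > ceiling
        if over.any():
            # rank-preserving infinitesimal spread just above the ceiling
            ranks = np.argsort(np.argsort(raw[over]))
            raw[over] = ceiling * (1.0 + 1e-9 * (ranks + 1))
    out.set_intensities(raw)
    out.log_base = None
    out.provenance = ["simulated_raw"]
    return out


class Benchmark(NamedTuple):
    """A cross-platform prediction task bundle."""

    train: PBMSample          # platform A, raw intensities (with artifacts)
    target_design: PBMSample  # platform B, sequences only
    target_truth: PBMSample   # platform B, raw measured intensities
    planted_model: AffinityModel  # ground-truth alpha over planted features
    target_clean_log: np.ndarray  # artifact-free log intensities on B


def make_benchmark(config: SimulationConfig) -> Benchmark:
    """Train-on-A / predict-on-B bundle sharing the planted affinities."""
    planted = config.planted or default_planted_features(
        config.seed, forbidden_contexts=(config.flank_a, config.flank_b))
    cfg = SimulationConfig(**{**config.__dict__, "planted": planted})

    design_a = simulate_design(cfg.n_probes_a, cfg.probe_length, cfg.flank_a,
                               seed=cfg.seed, prefix="A")
    design_b = simulate_design(cfg.n_probes_b, cfg.probe_length, cfg.flank_b,
                               seed=cfg.seed + 1, prefix="B")
    train = simulate_intensities(design_a, cfg, seed=cfg.seed + 2)
    truth = simulate_intensities(design_b, cfg, seed=cfg.seed + 3)
    clean_b = planted_log_intensities(design_b.sequences(), planted,
                                      cfg.background_mean)

    from .kmers import KmerSet  # local import to avoid cycle at module load
    kset = KmerSet([f for f, _ in planted])
    truth_model = AffinityModel(
        kmer_set=kset,
        alpha=np.array([a for _, a in planted]),
        intercept=0.0,
        training_mean=cfg.background_mean,
        cg_iterations=0,
        variant="planted",
        log_base=cfg.log_base,
        training_probe_length=len(design_a.sequences()[0]),
    )
    return Benchmark(train, design_b, truth, truth_model, clean_b)


def simulate_replicates(design: PBMSample, config: SimulationConfig,
                        n_replicates: int = 3) -> list[PBMSample]:
    """Independent technical replicates of one hybridization (same design
    and clean signal, fresh noise draws)."""
    reps = []
    for i in range(n_replicates):
        rep = simulate_intensities(design, config, seed=config.seed + 100 + i)
        rep.name = f"{design.name}_rep{i + 1}"
        reps.append(rep)
    return reps
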