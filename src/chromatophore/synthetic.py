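"""Seeded generators for synthetic study inputs.

Every pipeline stage can be exercised without the study's deposited raw
data: these generators produce inputs with the statistical structure each
stage assumes, always alongside the ground truth used to produce them, and
byte-identical under a fixed seed.

- proteomes of random sequences whose K/R content controls expected tryptic
  peptide counts;
- spectral-count tables drawn multinomially with observation probability
  ∝ abundance × expected peptide count (larger proteins yield more
  observable peptides — the assumption that makes peptide scaling the
  correct inverse), with per-sample loading distortions;
- truncated-normal layer-thickness measurement lists (defaults: cytoplasm
  116 ± 102 nm, n = 292; membrane 71 ± 14 nm, n = 237);
- two-state titration absorbance series over pH 1.9–8.9;
- movies of an expanding iridescent disc whose fill color follows the
  thin-film interference model at up to 15× areal expansion.

One global seed derives independent per-generator substreams, so modules
remain reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chromatophore.digest import ProteinRecord
from chromatophore.imaging import DEFAULT_FRAME_INTERVAL_S, FrameStack
from chromatophore.optics import (
    CYTOPLASM_MEAN_NM,
    CYTOPLASM_SD_NM,
    MEMBRANE_MEAN_NM,
    MEMBRANE_SD_NM,
    N_CYTOPLASM,
    N_MEMBRANE,
    LayerStack,
    ThicknessDistribution,
    expand_layers,
    spectrum_to_srgb,
    transfer_matrix_reflectance,
)
from chromatophore.pigments import TitrationSeries, titration_model

_AA = np.array(list("ACDEFGHILMNQSTVWY"))  # non-K/R/P residues

_STREAMS = {
    "proteome": 0,
    "counts": 1,
    "layers": 2,
    "titration": 3,
    "movie": 4,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator substream for one named generator."""
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def make_proteome(
    n: int,
    mean_length: int = 350,
    seed: int = 0,
    kr_freq: float = 0.08,
    p_freq: float = 0.05,
) -> list[ProteinRecord]:
    """Random protein records with configurable K/R and P frequencies.

    Lengths are Poisson-distributed around ``mean_length`` (floored at 20
    residues).  The expected tryptic peptide count of a length-L sequence is
    approximately ``1 + (L−1)·p_KR·(1−p_P)``, so ``kr_freq`` spans a wide
    range of expected counts.
    """
    if n < 1:
        raise ValueError("proteome size must be >= 1")
    if kr_freq + p_freq > 1:
        raise ValueError("kr_freq + p_freq must not exceed 1")
    rng = substream(seed, "proteome")
    records = []
    other = 1.0 - kr_freq - p_freq
    letters = np.concatenate([np.array(list("KRP")), _AA])
    probs = np.concatenate(
        [[kr_freq / 2, kr_freq / 2, p_freq], np.full(len(_AA), other / len(_AA))]
    )
    for i in range(n):
        length = max(20, int(rng.poisson(mean_length)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(
            ProteinRecord(id=f"SYN{i:04d}", sequence=seq, description=f"synthetic protein {i}")
        )
    return records


def make_count_table(
    proteome: Sequence[ProteinRecord],
    abundances: Sequence[float],
    depths: dict[str, int],
    loading_multipliers: dict[str, float] | None = None,
    seed: int = 0,
    k_p: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Multinomial spectral-count table with per-sample loading distortion.

    Observation probability is ∝ ``a_p · k_p``; each sample's total count is
    ``depth × loading multiplier``.  Returns the table and a ground-truth
    dict (abundances, k_p, per-protein probabilities).
    """
    from chromatophore.digest import expected_peptide_count

    a = np.asarray(abundances, dtype=float)
    if len(a) != len(proteome):
        raise ValueError("abundance vector length must match the proteome")
    if (a <= 0).any():
        raise ValueError("abundances must be positive")
    if any(d < 1 for d in depths.values()):
        raise ValueError("sequencing depths must be >= 1")
    a = a / a.sum()
    if k_p is None:
        k_p = [expected_peptide_count(p) for p in proteome]
    k = np.asarray(k_p, dtype=float)
    probs = a * k
    probs = probs / probs.sum()
    multipliers = loading_multipliers or {s: 1.0 for s in depths}
    rng = substream(seed, "counts")
    data = {}
    for sample, depth in depths.items():
        total = int(round(depth * multipliers.get(sample, 1.0)))
        data[sample] = rng.multinomial(total, probs)
    table = pd.DataFrame(data, index=[p.id for p in proteome])
    truth = {"abundances": a, "k_p": k, "probs": probs, "multipliers": multipliers}
    return table, truth


def make_layer_measurements(
    mean: float = CYTOPLASM_MEAN_NM,
    sd: float = CYTOPLASM_SD_NM,
    n: int = 292,
    seed: int = 0,
    lower_bound: float = 10.0,
) -> np.ndarray:
    """Truncated-normal layer thickness measurements (nm).

    Defaults reproduce the cytoplasm-layer design (116 ± 102 nm, n = 292);
    use 71/14/237 for the membrane layers.
    """
    if n < 1:
        raise ValueError("measurement count must be >= 1")
    dist = ThicknessDistribution(mean=mean, sd=sd, lower_bound=lower_bound)
    return dist.sample(n, substream(seed, "layers"))


def make_titration_series(
    pk: float = 5.0,
    a_acid: float = 0.15,
    a_base: float = 1.0,
    slope: float = 1.0,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    ph_min: float = 1.9,
    ph_max: float = 8.9,
) -> TitrationSeries:
    """Two-state titration absorbance series with optional Gaussian noise.

    The default pH grid spans 1.9–8.9, the experimental titration range.
    """
    if n_points < 4:
        raise ValueError("a titration series needs >= 4 points")
    ph = np.linspace(ph_min, ph_max, n_points)
    ab = titration_model(pk, a_acid, a_base, slope, ph)
    if noise_sd > 0:
        rng = substream(seed, "titration")
        ab = ab + rng.normal(0.0, noise_sd, size=ab.shape)
    return TitrationSeries(ph=ph, absorbance=np.clip(ab, 0.0, None))


@dataclass(frozen=True)
class MovieConfig:
    """Geometry and optics of a synthetic expanding-disc movie.

    The disc's areal expansion ramps linearly from 1 to
    ``max_areal_expansion`` (the study's chromatocytes reach ~15×); its
    radius scales with the square root of the areal factor and its fill
    color follows the thin-film model of the expanding sheath-cell stack.
    """

    seed: int = 0
    n_frames: int = 30
    height: int = 64
    width: int = 64
    base_radius_px: float = 16.0
    max_areal_expansion: float = 15.0
    noise_sd: float = 0.0
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    d_a_nm: float = CYTOPLASM_MEAN_NM
    d_b_nm: float = MEMBRANE_MEAN_NM
    n_pairs: int = 8
    n_a: float = N_CYTOPLASM
    n_b: float = N_MEMBRANE
    background_rgb: tuple[float, float, float] = (30.0, 30.0, 30.0)
    membrane_fixed: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("movie needs at least one frame")
        if self.max_areal_expansion < 1:
            raise ValueError("areal expansion must be >= 1")
        if self.base_radius_px <= 0 or self.height < 1 or self.width < 1:
            raise ValueError("invalid movie geometry")
        max_radius = self.base_radius_px * np.sqrt(self.max_areal_expansion)
        if max_radius > min(self.height, self.width):
            raise ValueError(
                "expanded disc radius exceeds the frame; enlarge the frame "
                "or shrink base_radius_px"
            )


def make_movie(config: MovieConfig) -> tuple[FrameStack, np.ndarray]:
    """Render an expanding iridescent disc.

    Per frame, the sheath-cell stack is thinned by the current areal factor,
    its reflectance computed by the transfer-matrix method, rendered to
    sRGB, and painted as a disc of radius ∝ √factor; additive Gaussian pixel
    noise is applied last.  Returns the frame stack and the ground-truth
    (T, 3) color timeline in 0–255 units.
    """
    cfg = config
    rng = substream(cfg.seed, "movie")
    base = LayerStack.alternating(
        cfg.d_a_nm, cfg.d_b_nm, cfg.n_pairs, n_a=cfg.n_a, n_b=cfg.n_b
    )
    if cfg.n_frames == 1:
        factors = np.array([1.0])
    else:
        factors = np.linspace(1.0, cfg.max_areal_expansion, cfg.n_frames)

    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    cy, cx = (cfg.height - 1) / 2.0, (cfg.width - 1) / 2.0
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2

    frames = np.empty((cfg.n_frames, cfg.height, cfg.width, 3))
    truth = np.empty((cfg.n_frames, 3))
    for t, f in enumerate(factors):
        stack = expand_layers(base, f, membrane_fixed=cfg.membrane_fixed)
        spectrum = transfer_matrix_reflectance(stack)
        color = np.array(spectrum_to_srgb(spectrum).as_tuple()) * 255.0
        truth[t] = color
        radius = cfg.base_radius_px * np.sqrt(f)
        frame = np.empty((cfg.height, cfg.width, 3))
        frame[:] = np.asarray(cfg.background_rgb, dtype=float)
        frame[dist2 <= radius**2] = color
        frames[t] = frame
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 255.0)
    return FrameStack(frames=frames, frame_interval_s=cfg.frame_interval_s), truth
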