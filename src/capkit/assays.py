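"""Closed-form assay computations: phagocytic index, tumor volumes,
relative growth, limit-of-detection censoring and the antisense sRNA
design rule."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhagocytosisCounts",
    "TumorMeasurement",
    "phagocytic_index",
    "tumor_volume",
    "relative_growth",
    "censor_lod",
    "design_srna",
    "reverse_complement",
]


@dataclass(frozen=True)
class PhagocytosisCounts:
    """Counts from confocal images of a macrophage-uptake assay."""

    engulfed_total: int
    macrophages_counted: int
    macrophages_with_bacteria: int

    def __post_init__(self) -> None:
        if min(self.engulfed_total, self.macrophages_counted,
               self.macrophages_with_bacteria) < 0:
            raise ValueError("counts must be non-negative")
        if self.macrophages_with_bacteria > self.macrophages_counted:
            raise ValueError("macrophages_with_bacteria cannot exceed "
                             "macrophages_counted")


def phagocytic_index(c: PhagocytosisCounts) -> float:
    """(engulfed / counted) * (containing / counted) * 100."""
    if c.macrophages_counted == 0:
        raise ValueError("macrophages_counted must be positive")
    n = c.macrophages_counted
    return (c.engulfed_total / n) * (c.macrophages_with_bacteria / n) * 100.0


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement with the volume model tag.

    ``lwh_half``: V = L*W*H*0.5 (subcutaneous tumors);
    ``lw2_half``: V = L*W^2*0.5 (spontaneous mammary tumors, whose
    z-dimension is too variable to caliper).
    """

    length: float
    width: float
    height: float | None = None
    model: str = "lwh_half"

    def __post_init__(self) -> None:
        if self.model not in ("lwh_half", "lw2_half"):
            raise ValueError("model must be 'lwh_half' or 'lw2_half'")
        if self.length <= 0 or self.width <= 0:
            raise ValueError("dimensions must be positive")
        if self.height is not None and self.height <= 0:
            raise ValueError("dimensions must be positive")


def tumor_volume(m: TumorMeasurement) -> float:
    """Tumor volume in mm^3 per the measurement's model tag."""
    if m.model == "lwh_half":
        if m.height is None:
            raise ValueError("lwh_half model requires a height")
        return m.length * m.width * m.height * 0.5
    return m.length * m.width ** 2 * 0.5


def relative_growth(volumes, t0_index: int = 0,
                    percent: bool = False) -> np.ndarray:
    """Tumor volumes normalized to the pre-injection baseline.

    Returns v(t)/v(t0), or (v(t)/v(t0) - 1)*100 with ``percent=True``.
    """
    v = np.asarray(volumes, dtype=float)
    baseline = v[t0_index]
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    rel = v / baseline
    return (rel - 1.0) * 100.0 if percent else rel


def censor_lod(values, lod: float) -> tuple[np.ndarray, np.ndarray]:
    """Apply limit-of-detection censoring to a series of counts.

    Values strictly below the LOD are replaced by the LOD with the
    censored flag set; values at the LOD count as observed (a colony at
    the detection floor was detected).
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    censored = v < lod
    return np.where(censored, lod, v), censored


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def design_srna(target_seq: str, start_codon_index: int,
                window: int = 24, anchor_offset: int = 0) -> str:
    """Antisense sRNA for translation knockdown of a target gene.

    Selects the ``window``-nt stretch of the target ending with the third
    base of the start codon — covering the upstream ribosome-binding-site
    region and the start codon — and returns its reverse complement.
    ``anchor_offset`` shifts the window 3' by that many bases.
    """
    seq = target_seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("target sequence must be over {A, C, G, T}")
    end = start_codon_index + 3 + anchor_offset
    start = end - window
    if start < 0 or end > len(seq):
        raise ValueError(f"{window}-nt window [{start}, {end}) falls outside "
                         "the target sequence")
    codon = seq[start_codon_index:start_codon_index + 3]
    if codon not in ("ATG", "GTG"):
        warnings.warn(f"start codon at index {start_codon_index} is {codon}, "
                      "not ATG/GTG", stacklevel=2)
    return reverse_complement(seq[start:end])
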