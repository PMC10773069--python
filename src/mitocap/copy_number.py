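"""mtDNA copy-number estimation from sequencing depth.

CN = mtDNA mean depth / mean depth of six nuclear reference loci * 2,
i.e. mitochondrial copies per (diploid) cell.  The identity of the six
nuclear loci is configuration — it does not enter the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import DepthProfile
from .errors import InvalidParameterError, UndefinedValueError

N_REFERENCE_LOCI = 6


@dataclass(frozen=True)
class CNEstimate:
    mt_mean_depth: float
    nuclear_depths: tuple[float, ...]
    nuclear_mean: float
    cn: float


def estimate_cn(
    mt_mean_depth: float,
    nuclear_depths,
    allow_any_arity: bool = False,
) -> CNEstimate:
    """mtDNA copy number from mitochondrial and nuclear mean depths.

    ``nuclear_depths`` are the per-locus mean depths of the six nuclear
    reference loci (arithmetic mean is taken); any other locus count requires
    the explicit ``allow_any_arity`` override.
    """
    depths = tuple(float(d) for d in nuclear_depths)
    if mt_mean_depth <= 0:
        raise InvalidParameterError("mt_mean_depth must be positive")
    if any(d < 0 for d in depths):
        raise InvalidParameterError("nuclear depths must be non-negative")
    if len(depths) != N_REFERENCE_LOCI and not allow_any_arity:
        raise InvalidParameterError(
            f"expected {N_REFERENCE_LOCI} nuclear loci, got {len(depths)} "
            "(pass allow_any_arity=True to override)"
        )
    if not depths:
        raise InvalidParameterError("at least one nuclear locus is required")
    nuclear_mean = float(np.mean(depths))
    if nuclear_mean == 0:
        raise UndefinedValueError("nuclear mean depth is zero")
    return CNEstimate(
        mt_mean_depth=float(mt_mean_depth),
        nuclear_depths=depths,
        nuclear_mean=nuclear_mean,
        cn=float(mt_mean_depth) / nuclear_mean * 2.0,
    )


def mt_mean_depth(profile: DepthProfile) -> float:
    """Mean coverage of the entire mtDNA genome.

    Zero-coverage positions count in the denominator: total aligned bases
    divided by reference length.
    """
    if profile.ref_length <= 0:
        raise InvalidParameterError("profile has non-positive reference length")
    return profile.mean


def read_nuclear_depths_tsv(path) -> tuple[float, ...]:
    """Read per-locus nuclear depths from a TSV with columns locus_name, mean_depth."""
    df = pd.read_csv(path, sep="\t")
    if "mean_depth" not in df.columns:
        raise InvalidParameterError("nuclear depth TSV needs a 'mean_depth' column")
    return tuple(float(x) for x in df["mean_depth"])
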