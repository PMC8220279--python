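"""Column schemas and random-stream helpers shared across the pipeline.

Every tabular interchange format in the package is a tidy :class:`pandas.DataFrame`
written as plain CSV. The canonical per-egg phenotype table has one row per egg and
the columns in :data:`EGG_TABLE_COLUMNS`; the ten phenotype metrics themselves are
:data:`METRIC_COLUMNS`, in the fixed order used for all multivariate computations
(four sum-standardized cone catches, luminance, five pattern metrics).
"""

from __future__ import annotations

import zlib

import numpy as np

#: The four single-cone photon-catch channels, standardized to sum to one per egg.
CONE_COLUMNS = ["q_uv", "q_sw", "q_mw", "q_lw"]

#: The five granularity/segmentation pattern metrics plus luminance, each
#: standardized within family as a proportion of the family maximum.
PATTERN_COLUMNS = ["marking_size", "dominance", "contrast", "coverage", "dispersion"]

#: The ten metrics defining an egg's position in multi-dimensional phenotypic space.
METRIC_COLUMNS = CONE_COLUMNS + ["luminance_std"] + PATTERN_COLUMNS

#: Bookkeeping columns of the per-egg phenotype table.
ID_COLUMNS = ["species", "family", "clutch_id", "egg_id"]

#: Clutch-level parasitism indicator and species-level elsewhere-in-range record.
PARASITISM_COLUMNS = ["parasitized", "parasitized_elsewhere"]

EGG_TABLE_COLUMNS = ID_COLUMNS + METRIC_COLUMNS + PARASITISM_COLUMNS

#: Per-species signature table columns (output of signature_metrics).
SIGNATURE_COLUMNS = [
    "species",
    "family",
    "consistency",
    "entropy",
    "absolute_distinctiveness",
    "combinatorial_distinctiveness",
    "mdps_distinctiveness",
    "n_clutches_used",
    "undefined_entropy",
]

#: Tidy model-results table columns (output of comparative_models.run_full_battery).
RESULT_COLUMNS = [
    "model_id",
    "variant",
    "response",
    "term",
    "estimate",
    "se",
    "t",
    "df",
    "p",
    "lambda",
    "n",
    "note",
]

CLUTCH_SIZE_MIN = 1
CLUTCH_SIZE_MAX = 5


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream derived from ``seed``.

    Each (seed, name) pair yields an independent :class:`numpy.random.Generator`,
    so adding a new consumer of randomness never perturbs the draws of existing
    ones. Names are hashed with CRC-32 into the seed sequence's spawn key.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
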