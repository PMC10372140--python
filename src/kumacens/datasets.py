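"""Packaged example datasets."""

from importlib import resources

import numpy as np

__all__ = ["load_shasta"]


def load_shasta() -> np.ndarray:
    """Monthly water capacity of the Shasta reservoir (California), as a
    proportion of total capacity, for February of each year 1991-2010.

    Twenty values in (0, 1); the classic worked example for bounded
    hydrological data.
    """
    path = resources.files("kumacens.data") / "shasta_feb_1991_2010.csv"
    with path.open() as fh:
        next(fh)  # header
        return np.array([float(line) for line in fh if line.strip()])
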