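"""Bundled datasets."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["RemissionDataset", "load_remission_data"]

_REMISSION_SHA256 = "576bb4230f7d60151581a47f3efe51f34c3b8878234b2d9ffc5d12d2e9113362"


@dataclass(frozen=True)
class RemissionDataset:
    """Remission times (months) of 128 bladder cancer patients."""

    values: np.ndarray
    label: str = "bladder_cancer_remission"

    @property
    def size(self) -> int:
        return int(self.values.size)


def load_remission_data() -> RemissionDataset:
    """Load the bundled bladder-cancer remission times.

    128 positive remission durations in months, shortest 0.08 and longest
    79.05, in their original order.  The fixture file is checksummed; a
    mismatch raises rather than returning silently corrupted data.
    """
    ref = resources.files("maxerlb").joinpath("data/bladder_remission.txt")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _REMISSION_SHA256:
        raise RuntimeError(
            f"remission dataset fixture corrupted: sha256 {digest} != {_REMISSION_SHA256}"
        )
    values = np.array(
        [float(line) for line in raw.decode().splitlines() if line.strip() and not line.startswith("#")]
    )
    return RemissionDataset(values=values)
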