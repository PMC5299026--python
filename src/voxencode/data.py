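"""Block-structured data model for continuous-design encoding experiments.

A continuous-design fMRI experiment presents an uninterrupted stimulus stream
(e.g. natural movies) while BOLD responses are sampled once per repetition
time. Data arrive as *blocks*: paired feature (T x p) and response (T x m)
matrices sampled on a common 1 Hz grid, labelled ``train``, ``validation`` or
``test``. Test blocks may carry repeated measurements (R x T x m) of the same
stimulus, which are what make noise-ceiling estimation possible.

Conventions: sample ``t`` covers the interval [t, t+1) seconds, indices are
0-based and block-local, and no operation lets information cross a block
boundary. Responses are assumed motion-corrected and detrended upstream;
z-scoring is the only amplitude normalisation performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FeatureBlock",
    "ResponseBlock",
    "EncodingDataset",
    "preprocess",
    "split_validation",
    "average_repeats",
    "save_dataset",
    "load_dataset",
    "export_tsv",
    "load_nifti_responses",
]

ROLES = ("train", "validation", "test")


class DataFormatError(ValueError):
    """Raised when an on-disk container is malformed or inconsistent."""


@dataclass(frozen=True)
class FeatureBlock:
    """A (T x p) matrix of stimulus features, one row per second."""

    values: np.ndarray
    block_id: str
    role: str = "train"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1:
            raise ValueError(f"feature block {self.block_id!r}: need a T x p matrix with T >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"feature block {self.block_id!r}: non-finite values")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ResponseBlock:
    """A (T x m) matrix of voxel responses, optionally with repeats.

    ``repeats`` (R x T x m), when present, holds the individual repeated
    measurements; ``values`` must then equal their mean over the repeat axis.
    """

    values: np.ndarray
    block_id: str
    repeats: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1:
            raise ValueError(f"response block {self.block_id!r}: need a T x m matrix with T >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"response block {self.block_id!r}: non-finite values")
        if self.repeats is not None:
            repeats = np.asarray(self.repeats, dtype=float)
            object.__setattr__(self, "repeats", repeats)
            if repeats.ndim != 3 or repeats.shape[1:] != values.shape:
                raise ValueError(
                    f"response block {self.block_id!r}: repeats must be R x T x m "
                    f"matching values {values.shape}"
                )
            if repeats.shape[0] < 2:
                raise ValueError(f"response block {self.block_id!r}: need R >= 2 repeats")
            if not np.allclose(values, repeats.mean(axis=0), atol=1e-10):
                raise ValueError(
                    f"response block {self.block_id!r}: values must equal the repeat mean"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EncodingDataset:
    """Paired feature/response blocks plus voxel group labels.

    Pairing is 1:1 by ``block_id``. ``voxel_groups`` assigns every voxel to
    exactly one group (the analogue of an area x subject cell); models in the
    recurrent family share their recurrent trunk within a group.
    """

    features: tuple[FeatureBlock, ...]
    responses: tuple[ResponseBlock, ...]
    voxel_groups: tuple[str, ...]
    sampling_interval: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "responses", tuple(self.responses))
        object.__setattr__(self, "voxel_groups", tuple(self.voxel_groups))
        fids = [b.block_id for b in self.features]
        rids = [b.block_id for b in self.responses]
        if sorted(fids) != sorted(rids):
            raise DataFormatError(
                f"feature/response block ids differ: {sorted(set(fids) ^ set(rids))}"
            )
        if len(set(fids)) != len(fids):
            raise DataFormatError("duplicate block ids")
        rmap = {b.block_id: b for b in self.responses}
        p = {b.n_features for b in self.features}
        if len(p) > 1:
            raise ValueError(f"inconsistent feature dimensionality across blocks: {sorted(p)}")
        m = len(self.voxel_groups)
        for fb in self.features:
            rb = rmap[fb.block_id]
            if rb.n_samples != fb.n_samples:
                raise ValueError(f"block {fb.block_id!r}: feature/response length mismatch")
            if rb.n_voxels != m:
                raise ValueError(
                    f"block {fb.block_id!r}: {rb.n_voxels} voxels but {m} group labels"
                )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.features[0].n_features

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_groups)

    def response_for(self, block_id: str) -> ResponseBlock:
        return next(b for b in self.responses if b.block_id == block_id)

    def blocks(self, role: str | None = None):
        """Yield (FeatureBlock, ResponseBlock) pairs, optionally by role."""
        rmap = {b.block_id: b for b in self.responses}
        for fb in self.features:
            if role is None or fb.role == role:
                yield fb, rmap[fb.block_id]

    def concatenated(self, role: str):
        """Stack all blocks of a role into one (T x p), (T x m) pair."""
        pairs = list(self.blocks(role))
        if not pairs:
            raise ValueError(f"no blocks with role {role!r}")
        X = np.concatenate([fb.values for fb, _ in pairs], axis=0)
        Y = np.concatenate([rb.values for _, rb in pairs], axis=0)
        return X, Y

    def group_indices(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(self.voxel_groups):
            groups.setdefault(g, []).append(i)
        return {g: np.asarray(ix) for g, ix in groups.items()}


# -- preprocessing -----------------------------------------------------------


def preprocess(
    dataset: EncodingDataset, discard_seconds: int = 6, zscore: bool = True
) -> EncodingDataset:
    """Discard each block's initial transient and z-score responses per block.

    The first ``discard_seconds`` samples of every block are dropped (the
    stimulus onset transient is unmodelled). If ``zscore`` is set, each voxel's
    response is standardised to zero mean and unit variance within each block;
    repeats are mapped through the same per-block affine transform so they
    remain consistent with their mean. Constant channels are set to zero with
    a warning. The input dataset is never mutated.
    """
    discard = int(round(discard_seconds / dataset.sampling_interval))
    for fb in dataset.features:
        if discard >= fb.n_samples:
            raise ValueError(
                f"block {fb.block_id!r}: cannot discard {discard_seconds} s from "
                f"a {fb.n_samples}-sample block"
            )
    new_features = [replace(fb, values=fb.values[discard:]) for fb in dataset.features]
    new_responses = []
    for rb in dataset.responses:
        values = rb.values[discard:]
        repeats = None if rb.repeats is None else rb.repeats[:, discard:, :]
        if zscore:
            mu = values.mean(axis=0)
            sd = values.std(axis=0)
            constant = sd < 1e-12
            if constant.any():
                warnings.warn(
                    f"block {rb.block_id!r}: {int(constant.sum())} constant voxel(s) "
                    "set to zero during z-scoring",
                    stacklevel=2,
                )
            sd = np.where(constant, 1.0, sd)
            values = (values - mu) / sd
            values[:, constant] = 0.0
            if repeats is not None:
                # same affine map keeps the repeat mean equal to `values`
                repeats = (repeats - mu) / sd
        new_responses.append(ResponseBlock(values=values, block_id=rb.block_id, repeats=repeats))
    return EncodingDataset(
        features=new_features,
        responses=new_responses,
        voxel_groups=dataset.voxel_groups,
        sampling_interval=dataset.sampling_interval,
    )


def split_validation(
    dataset: EncodingDataset, tail_seconds: int = 45
) -> tuple[EncodingDataset, EncodingDataset]:
    """Carve the final ``tail_seconds`` of every training block into a validation set.

    Returns ``(train, validation)`` datasets. Non-training blocks stay with the
    training dataset untouched. Concatenating each train block with its
    validation tail restores the original block exactly.
    """
    tail = int(round(tail_seconds / dataset.sampling_interval))
    rmap = {b.block_id: b for b in dataset.responses}
    train_f, train_r, val_f, val_r = [], [], [], []
    for fb in dataset.features:
        rb = rmap[fb.block_id]
        if fb.role != "train":
            train_f.append(fb)
            train_r.append(rb)
            continue
        if tail >= fb.n_samples:
            raise ValueError(
                f"block {fb.block_id!r}: validation tail of {tail_seconds} s does not "
                f"leave any training samples in a {fb.n_samples}-sample block"
            )
        cut = fb.n_samples - tail
        train_f.append(replace(fb, values=fb.values[:cut]))
        train_r.append(ResponseBlock(values=rb.values[:cut], block_id=rb.block_id))
        if tail > 0:
            val_f.append(
                FeatureBlock(values=fb.values[cut:], block_id=fb.block_id, role="validation")
            )
            val_r.append(ResponseBlock(values=rb.values[cut:], block_id=rb.block_id))
    train = EncodingDataset(
        features=train_f,
        responses=train_r,
        voxel_groups=dataset.voxel_groups,
        sampling_interval=dataset.sampling_interval,
    )
    if val_f:
        validation = EncodingDataset(
            features=val_f,
            responses=val_r,
            voxel_groups=dataset.voxel_groups,
            sampling_interval=dataset.sampling_interval,
        )
    else:
        validation = None
    return train, validation


def average_repeats(block: ResponseBlock) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error over the repeat axis of a test block.

    Returns ``(mean, sem)``, both (T x m). The SEM uses the sample standard
    deviation (ddof=1) divided by sqrt(R).
    """
    if block.repeats is None:
        raise ValueError(f"block {block.block_id!r} has no repeats")
    repeats = block.repeats
    R = repeats.shape[0]
    if R < 2:
        raise ValueError("need at least 2 repeats")
    mean = repeats.mean(axis=0)
    sem = repeats.std(axis=0, ddof=1) / np.sqrt(R)
    return mean, sem


# -- serialization -----------------------------------------------------------


def save_dataset(dataset: EncodingDataset, path) -> None:
    """Write a dataset to an HDF5 container.

    Layout: ``/blocks/<id>/features`` (T x p), ``/blocks/<id>/responses``
    (T x m), optional ``/blocks/<id>/repeats`` (R x T x m) with a ``role``
    attribute per block; ``/voxels/groups`` holds the m group labels;
    ``sampling_interval`` is a root attribute.
    """
    with h5py.File(path, "w") as f:
        f.attrs["sampling_interval"] = dataset.sampling_interval
        blocks = f.create_group("blocks")
        rmap = {b.block_id: b for b in dataset.responses}
        for fb in dataset.features:
            g = blocks.create_group(fb.block_id)
            g.attrs["role"] = fb.role
            g.create_dataset("features", data=fb.values)
            rb = rmap[fb.block_id]
            g.create_dataset("responses", data=rb.values)
            if rb.repeats is not None:
                g.create_dataset("repeats", data=rb.repeats)
        f.create_group("voxels").create_dataset(
            "groups", data=np.asarray(dataset.voxel_groups, dtype="S")
        )


def load_dataset(path) -> EncodingDataset:
    """Read a dataset written by :func:`save_dataset` (bit-exact round trip)."""
    features, responses = [], []
    with h5py.File(path, "r") as f:
        try:
            sampling_interval = float(f.attrs["sampling_interval"])
            groups = [s.decode() for s in f["voxels/groups"][()]]
            for block_id in f["blocks"]:
                g = f["blocks"][block_id]
                if "features" not in g or "responses" not in g:
                    raise DataFormatError(
                        f"block {block_id!r}: missing features or responses dataset"
                    )
                features.append(
                    FeatureBlock(
                        values=g["features"][()], block_id=block_id, role=g.attrs["role"]
                    )
                )
                responses.append(
                    ResponseBlock(
                        values=g["responses"][()],
                        block_id=block_id,
                        repeats=g["repeats"][()] if "repeats" in g else None,
                    )
                )
        except KeyError as exc:
            raise DataFormatError(f"malformed dataset container {path}: {exc}") from exc
    return EncodingDataset(
        features=features,
        responses=responses,
        voxel_groups=groups,
        sampling_interval=sampling_interval,
    )


def export_tsv(dataset: EncodingDataset, directory) -> None:
    """Export each block matrix as a TSV file (small-fixture interchange).

    One file per matrix (``<id>.features.tsv``, ``<id>.responses.tsv``),
    tab-separated with a header row of column indices and no row names, plus
    ``voxel_groups.tsv``. Repeats are not exported (HDF5 is the full-fidelity
    container).
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rmap = {b.block_id: b for b in dataset.responses}
    for fb in dataset.features:
        pd.DataFrame(fb.values).to_csv(
            directory / f"{fb.block_id}.features.tsv", sep="\t", index=False
        )
        pd.DataFrame(rmap[fb.block_id].values).to_csv(
            directory / f"{fb.block_id}.responses.tsv", sep="\t", index=False
        )
    pd.DataFrame({"group": list(dataset.voxel_groups)}).to_csv(
        directory / "voxel_groups.tsv", sep="\t", index=False
    )


def load_nifti_responses(volume_path, mask_path) -> np.ndarray:
    """Adapter for users with real data: 4-D NIfTI volume + 3-D mask -> (T x m).

    Requires nibabel. Voxels are ordered by the mask's flat (C-order) index.
    """
    import nibabel as nib

    vol = np.asarray(nib.load(str(volume_path)).dataobj)
    mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    return vol[mask].T
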