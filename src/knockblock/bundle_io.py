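"""HDF5 serialization of the per-block knockoff parameter ensemble.

The hand-off artifact from LD processing to summary-statistics inference
is one HDF5 file per block plus a top-level JSON manifest.  Each block
file stores, under ``/block_{i}/``:

* ``Sigma`` — floored, rescaled correlation matrix (p_i x p_i)
* ``S``     — key-level maximum-entropy matrix (|R| x |R|)
* ``D``     — full-dimensional sampling matrix (p_i x p_i)
* ``groups``      — 1-based group labels (length p_i)
* ``group_reps``  — 1-based key indices into the block
* ``m``           — knockoff copies per feature
* ``feasibility`` — [min eig(D), min eig(((m+1)/m) Sigma - D)]
* ``variants/{chrom,pos,id,ref,alt}`` — variant metadata

No per-sample data is written anywhere.  Files carry no timestamps
(datasets are created with ``track_times=False``) so identical inputs
produce byte-identical bundles; creation metadata lives only in the
manifest.  The manifest records the schema version, the sample size the
matrices were estimated from, and a SHA-256 checksum per file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .grouping import GroupStructure
from .knockoff_optim import FeasibilityReport, KnockoffParams, check_feasibility
from .ld_blocks import LDBlock

__all__ = ["BundleError", "write_bundle", "read_bundle", "MANIFEST_NAME"]

SCHEMA_VERSION = "1"
MANIFEST_NAME = "manifest.json"
SIGMA_SYM_TOL = 1e-10
SIGMA_DIAG_TOL = 1e-10
SIGMA_EIG_MIN = 1e-6
FEAS_TOL = 1e-8


class BundleError(ValueError):
    """Schema, integrity, or validation failure in an LD bundle."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix(grp: h5py.Group, name: str, arr: np.ndarray) -> None:
    grp.create_dataset(
        name, data=np.asarray(arr), compression="gzip", compression_opts=4,
        track_times=False,
    )


def _validate_block(
    block: LDBlock, groups: GroupStructure, params: KnockoffParams, index: int
) -> None:
    p = block.sigma.shape[0]
    if block.sigma.shape[1] != p:
        raise BundleError(f"block {index}: Sigma not square")
    if groups.membership.size != p:
        raise BundleError(
            f"block {index}: membership length {groups.membership.size} != p {p}"
        )
    if params.D.shape != (p, p):
        raise BundleError(f"block {index}: D is {params.D.shape}, expected {(p, p)}")
    r = groups.keys.size
    if params.S.shape != (r, r):
        raise BundleError(f"block {index}: S is {params.S.shape}, expected {(r, r)}")
    if len(block.variants) != p:
        raise BundleError(f"block {index}: variant table length mismatch")


def write_bundle(
    blocks: list[tuple[LDBlock, GroupStructure, KnockoffParams]],
    out_dir: str | Path,
    n_samples: int | None = None,
) -> Path:
    """Write the per-block ensemble to ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (block, groups, params) in enumerate(blocks, start=1):
        _validate_block(block, groups, params, i)
        fname = f"block_{i}.h5"
        path = out_dir / fname
        with h5py.File(path, "w", track_order=False) as fh:
            grp = fh.create_group(f"block_{i}", track_order=False)
            _write_matrix(grp, "Sigma", block.sigma)
            _write_matrix(grp, "S", params.S)
            _write_matrix(grp, "D", params.D)
            grp.create_dataset(
                "groups", data=groups.membership.astype(np.int64), track_times=False
            )
            grp.create_dataset(
                "group_reps", data=(groups.keys + 1).astype(np.int64),
                track_times=False,
            )
            grp.create_dataset("m", data=np.int64(params.m), track_times=False)
            feas = params.feasibility or check_feasibility(
                block.sigma, params.D, params.m
            )
            grp.create_dataset(
                "feasibility",
                data=np.array([feas.min_eig_D, feas.min_eig_slack]),
                track_times=False,
            )
            var = grp.create_group("variants", track_order=False)
            v = block.variants
            str_dtype = h5py.string_dtype(encoding="utf-8")
            var.create_dataset(
                "chrom", data=v["chrom"].astype(str).to_numpy(), dtype=str_dtype,
                track_times=False,
            )
            var.create_dataset(
                "pos", data=v["pos"].to_numpy(dtype=np.int64), track_times=False
            )
            for col in ("id", "ref", "alt"):
                var.create_dataset(
                    col, data=v[col].astype(str).to_numpy(), dtype=str_dtype,
                    track_times=False,
                )
        entries.append(
            {
                "file": fname,
                "block": i,
                "chrom": str(block.chrom),
                "n_variants": int(block.sigma.shape[0]),
                "n_keys": int(groups.keys.size),
                "sha256": _sha256(path),
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool": "knockblock",
        "tool_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "n_blocks": len(blocks),
        "n_samples": n_samples,
        "files": entries,
    }
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def _require(grp: h5py.Group, name: str, block: int):
    if name not in grp:
        raise BundleError(f"block {block}: missing dataset {name!r} (schema error)")
    return grp[name]


def read_bundle(
    path: str | Path, validate: bool = True
) -> list[tuple[LDBlock, GroupStructure, KnockoffParams]]:
    """Load and validate a bundle written by :func:`write_bundle`.

    ``path`` may be the bundle directory or its manifest file.  Validation
    re-checks file checksums, Sigma symmetry and unit diagonal, minimum
    eigenvalue, and the knockoff feasibility constraints; silently
    corrupted bundles are refused.
    """
    path = Path(path)
    manifest_path = path if path.is_file() else path / MANIFEST_NAME
    if not manifest_path.exists():
        raise BundleError(f"manifest not found at {manifest_path}")
    out_dir = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    result = []
    offset = 0
    for entry in manifest["files"]:
        fpath = out_dir / entry["file"]
        if not fpath.exists():
            raise BundleError(f"bundle file missing: {fpath}")
        if validate and _sha256(fpath) != entry["sha256"]:
            raise BundleError(f"checksum mismatch for {fpath} (integrity error)")
        i = entry["block"]
        with h5py.File(fpath, "r") as fh:
            if f"block_{i}" not in fh:
                raise BundleError(f"{fpath}: missing group block_{i} (schema error)")
            grp = fh[f"block_{i}"]
            sigma = _require(grp, "Sigma", i)[()]
            S = _require(grp, "S", i)[()]
            D = _require(grp, "D", i)[()]
            membership = _require(grp, "groups", i)[()]
            keys = _require(grp, "group_reps", i)[()] - 1
            m = int(_require(grp, "m", i)[()])
            feas_stored = _require(grp, "feasibility", i)[()]
            var_grp = _require(grp, "variants", i)
            variants = pd.DataFrame(
                {
                    "chrom": [s.decode() for s in var_grp["chrom"][()]],
                    "pos": var_grp["pos"][()],
                    "id": [s.decode() for s in var_grp["id"][()]],
                    "ref": [s.decode() for s in var_grp["ref"][()]],
                    "alt": [s.decode() for s in var_grp["alt"][()]],
                }
            )
        p = sigma.shape[0]
        if validate:
            _validate_matrices(sigma, D, m, i)
        block = LDBlock(
            start=offset, stop=offset + p, chrom=str(entry.get("chrom", "NA")),
            sigma=sigma, variants=variants,
        )
        groups = GroupStructure(membership=membership, keys=np.asarray(keys))
        params = KnockoffParams(
            S=S, D=D, m=m,
            feasibility=FeasibilityReport(
                min_eig_D=float(feas_stored[0]),
                min_eig_slack=float(feas_stored[1]),
                m=m,
            ),
        )
        result.append((block, groups, params))
        offset += p
    return result


def _validate_matrices(sigma: np.ndarray, D: np.ndarray, m: int, i: int) -> None:
    if np.abs(sigma - sigma.T).max() > SIGMA_SYM_TOL:
        raise BundleError(f"block {i}: Sigma not symmetric")
    if np.abs(np.diag(sigma) - 1.0).max() > SIGMA_DIAG_TOL:
        raise BundleError(f"block {i}: Sigma diagonal deviates from 1")
    sig_min = float(np.linalg.eigvalsh(sigma)[0])
    if sig_min < SIGMA_EIG_MIN:
        raise BundleError(
            f"block {i}: Sigma min eigenvalue {sig_min:.3e} < {SIGMA_EIG_MIN:g}"
        )
    report = check_feasibility(sigma, D, m)
    if report.min_eig_D < -FEAS_TOL or report.min_eig_slack < -FEAS_TOL:
        raise BundleError(
            f"block {i}: knockoff feasibility violated "
            f"(min eig(D) = {report.min_eig_D:.3e}, "
            f"min eig(((m+1)/m) Sigma - D) = {report.min_eig_slack:.3e})"
        )
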