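"""Readers and writers for skeleton sequences.

Two formats:

* the NTU RGB+D ``.skeleton`` plain-text format (frame count; per frame a body
  count, then per body a header line, a joint count, and one line per joint
  whose first three whitespace-separated fields are x y z in meters);
* an internal fixture format — a ``.npz`` container with named arrays —
  used for synthetic datasets and checkpoint-adjacent artifacts.
"""

from __future__ import annotations

import logging
import zipfile
from pathlib import Path

import numpy as np

from .skeleton import SkeletonGraph, SkeletonSequence

__all__ = ["read_ntu_skeleton", "write_fixture", "read_fixture", "SkeletonParseError"]

logger = logging.getLogger(__name__)


class SkeletonParseError(ValueError):
    """Malformed ``.skeleton`` or fixture file; message carries the line number."""


class _Lines:
    def __init__(self, path):
        self.path = str(path)
        with open(path) as fh:
            self.lines = fh.read().splitlines()
        self.pos = 0

    def next(self, what: str) -> str:
        if self.pos >= len(self.lines):
            raise SkeletonParseError(
                f"{self.path}: unexpected end of file at line {self.pos + 1} "
                f"while reading {what}"
            )
        line = self.lines[self.pos]
        self.pos += 1
        return line

    def next_int(self, what: str) -> int:
        lineno = self.pos + 1
        tok = self.next(what).split()
        if len(tok) < 1:
            raise SkeletonParseError(f"{self.path}:{lineno}: empty line, expected {what}")
        try:
            return int(tok[0])
        except ValueError:
            raise SkeletonParseError(
                f"{self.path}:{lineno}: expected integer {what}, got {tok[0]!r}"
            ) from None


def read_ntu_skeleton(path, graph: SkeletonGraph) -> SkeletonSequence:
    """Read an NTU RGB+D ``.skeleton`` text file into a sequence.

    Only the first tracked body is kept; multi-body files trigger a warning
    (the evaluation targets single-actor action classes). Joint indices in
    the file are implicit in line order and map directly onto the graph's
    0-based joint order.
    """
    lx = _Lines(path)
    n_frames = lx.next_int("frame count")
    if n_frames < 1:
        raise SkeletonParseError(f"{lx.path}:1: frame count must be >= 1, got {n_frames}")
    V = graph.joint_count
    coords = np.zeros((n_frames, V, 3))
    warned = False
    for t in range(n_frames):
        n_bodies = lx.next_int(f"body count of frame {t}")
        if n_bodies < 1:
            raise SkeletonParseError(
                f"{lx.path}:{lx.pos}: frame {t} declares {n_bodies} bodies"
            )
        if n_bodies > 1 and not warned:
            logger.warning(
                "%s: frame %d has %d bodies; keeping the first body only",
                lx.path, t, n_bodies,
            )
            warned = True
        for b in range(n_bodies):
            lx.next(f"body header of frame {t}")  # bodyID + tracking fields, unused
            n_joints = lx.next_int(f"joint count of frame {t}")
            if n_joints != V:
                raise SkeletonParseError(
                    f"{lx.path}:{lx.pos}: frame {t} body {b} declares "
                    f"{n_joints} joints, expected {V}"
                )
            for v in range(n_joints):
                lineno = lx.pos + 1
                fields = lx.next(f"joint {v} of frame {t}").split()
                if len(fields) < 3:
                    raise SkeletonParseError(
                        f"{lx.path}:{lineno}: joint line has {len(fields)} fields, "
                        "expected at least x y z"
                    )
                try:
                    xyz = [float(f) for f in fields[:3]]
                except ValueError:
                    raise SkeletonParseError(
                        f"{lx.path}:{lineno}: non-numeric coordinate in {fields[:3]}"
                    ) from None
                if b == 0:
                    coords[t, v] = xyz
    return SkeletonSequence(coords=coords, instance_id=Path(path).stem)


def write_fixture(seq: SkeletonSequence, path) -> None:
    """Write a sequence to the internal ``.npz`` fixture format (lossless)."""
    if seq.label is None:
        kind, label = "none", ""
    elif isinstance(seq.label, int):
        kind, label = "int", str(seq.label)
    else:
        kind, label = "str", str(seq.label)
    with open(path, "wb") as fh:  # handle keeps np.savez from appending .npz
        np.savez(
            fh,
            coords=seq.coords,
            label=np.asarray(label),
            label_kind=np.asarray(kind),
            instance_id=np.asarray(seq.instance_id),
        )


def read_fixture(path) -> SkeletonSequence:
    """Read a sequence written by :func:`write_fixture`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            if "coords" not in data:
                raise SkeletonParseError(f"{path}: fixture is missing the 'coords' array")
            coords = data["coords"]
            kind = str(data["label_kind"]) if "label_kind" in data else "none"
            raw = str(data["label"]) if "label" in data else ""
            label = None if kind == "none" else (int(raw) if kind == "int" else raw)
            instance_id = str(data["instance_id"]) if "instance_id" in data else ""
    except (zipfile.BadZipFile, ValueError, OSError) as exc:
        if isinstance(exc, SkeletonParseError):
            raise
        raise SkeletonParseError(f"{path}: not a fixture container ({exc})") from None
    return SkeletonSequence(coords=coords, label=label, instance_id=instance_id)
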