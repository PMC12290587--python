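"""File round-tripping: delimited signal text, dyad trial sets, manifests.

Signals are stored as plain delimited text — two numeric columns (one per
channel) preceded by a ``# fs=<Hz>`` header line — so that any preprocessed
continuous two-channel recording can be fed to the estimators without
binary EEG formats. Values are printed with 17 significant digits, which
round-trips IEEE doubles exactly.

All writes are atomic (write to a temporary file in the target directory,
then rename), so interrupted runs never leave truncated outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np

from .sigproc import ContinuousSignal
from .simulate import DyadTrialSet

__all__ = [
    "read_signal_file",
    "write_signal_file",
    "write_dyad_set",
    "read_dyad_set",
    "write_manifest",
    "read_manifest",
    "config_hash",
    "atomic_write_text",
]


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_signal_file(path, pair: tuple[ContinuousSignal, ContinuousSignal]) -> None:
    """Write a two-channel signal as delimited text with a ``# fs=`` header."""
    a, b = pair
    if a.fs != b.fs:
        raise ValueError("both channels must share the sampling rate")
    if len(a) != len(b):
        raise ValueError("both channels must have the same length")
    lines = [f"# fs={a.fs!r}"]
    lines.extend(
        f"{x:.17g}\t{y:.17g}" for x, y in zip(a.samples, b.samples)
    )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_signal_file(path) -> tuple[ContinuousSignal, ContinuousSignal]:
    """Read a two-channel delimited signal file written by
    :func:`write_signal_file` (or any conforming text file)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}:1: missing '# fs=<Hz>' header line")
        try:
            fs = float(first[len("# fs=") :].strip())
        except ValueError:
            raise ValueError(f"{path}:1: could not parse sampling rate") from None
        cols_a, cols_b = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 channel columns, got {len(parts)}"
                )
            try:
                cols_a.append(float(parts[0]))
                cols_b.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in row"
                ) from None
    return (
        ContinuousSignal(np.asarray(cols_a), fs),
        ContinuousSignal(np.asarray(cols_b), fs),
    )


def config_hash(config: object) -> str:
    """Deterministic short hash of a config dataclass (or mapping)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, entries: dict) -> None:
    """Write a plain-text ``key=value`` manifest (one entry per line)."""
    lines = [f"{k}={v}" for k, v in entries.items()]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_manifest(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key] = value
    return out


def write_dyad_set(tset: DyadTrialSet, directory) -> None:
    """Write one signal file per trial plus a manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(tset.ntrials - 1)))
    for i in range(tset.ntrials):
        write_signal_file(directory / f"trial_{i:0{width}d}.txt", tset.trial(i))
    entries = {"ntrials": tset.ntrials, "fs": repr(tset.fs)}
    entries.update({f"config.{k}": v for k, v in tset.config_dict().items()})
    entries["config_hash"] = config_hash(tset.config)
    write_manifest(directory / "manifest.txt", entries)


def read_dyad_set(directory) -> DyadTrialSet:
    """Inverse of :func:`write_dyad_set`; config is restored as a plain dict."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.txt")
    ntrials = int(manifest["ntrials"])
    config = {
        k[len("config.") :]: v for k, v in manifest.items() if k.startswith("config.")
    }
    trials = []
    fs = float(manifest["fs"])
    for path in sorted(directory.glob("trial_*.txt")):
        a, b = read_signal_file(path)
        trials.append(np.stack([a.samples, b.samples]))
    if len(trials) != ntrials:
        raise ValueError(
            f"{directory}: manifest lists {ntrials} trials, found {len(trials)}"
        )
    return DyadTrialSet(data=np.stack(trials), fs=fs, config=config)
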