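"""Reproducibility headers for output files.

Every table the CLI writes is preceded by ``#``-prefixed key/value lines
recording the command, configuration hash, weight profile, seeds, input
file digests and tool version, so a result can always be traced back to
exactly what produced it. Readers skip the block transparently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


@dataclass
class RunManifest:
    command: str
    config_digest: str = ""
    weights_profile: str = ""
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)

    def add_input(self, label: str, path: str | Path) -> None:
        self.inputs[f"input_{label}"] = f"{Path(path).name}:{file_digest(path)}"

    def header_lines(self) -> list[str]:
        items: dict[str, object] = {
            "tool": f"sscore {__version__}",
            "command": self.command,
        }
        if self.config_digest:
            items["config_digest"] = self.config_digest
        if self.weights_profile:
            items["weights"] = self.weights_profile
        if self.seed is not None:
            items["seed"] = self.seed
        items.update(self.inputs)
        items.update(self.extra)
        return [f"# {k}: {v}" for k, v in items.items()]


def write_table(df: pd.DataFrame, path: str | Path, manifest: RunManifest,
                index_label: str | None = "gene",
                float_format: str = "%.6g") -> None:
    """Write a TSV with the manifest as a leading comment block."""
    with open(path, "w") as fh:
        for line in manifest.header_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format=float_format,
                  index_label=index_label, lineterminator="\n")


def read_table(path: str | Path, index_col: int | None = 0,
               ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns the frame and
    the parsed header block."""
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col)
    return df, header
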