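"""Tabular artifacts with provenance headers.

Every CLI output table is a CSV whose leading ``#`` comment lines carry a
JSON provenance block (command, seed, config hash, package version).  Bodies
round-trip losslessly and are byte-identical for identical config and seed.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .. import __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TableArtifact:
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @classmethod
    def create(cls, data: pd.DataFrame, command: str = "",
               seed: int | None = None,
               config: dict | None = None) -> "TableArtifact":
        prov = {
            "command": command,
            "seed": seed,
            "config_hash": config_hash(config or {}),
            "version": __version__,
        }
        return cls(data=data, provenance=prov)

    def write_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("# provenance: "
                  + json.dumps(self.provenance, sort_keys=True) + "\n")
        self.data.to_csv(buf, index=False, lineterminator="\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read_csv(cls, path: str | Path) -> "TableArtifact":
        text = Path(path).read_text()
        provenance: dict = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("# provenance: "):
                provenance = json.loads(line[len("# provenance: "):])
            elif not line.startswith("#"):
                body_lines.append(line)
        data = pd.read_csv(io.StringIO("\n".join(body_lines)))
        return cls(data=data, provenance=provenance)
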