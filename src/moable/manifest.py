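"""Run manifests: every pipeline output directory records what produced it."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__

MANIFEST_NAME = "manifest.json"


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict,
                   seeds: dict, inputs: dict[str, str]) -> Path:
    """Write manifest.json: command, config snapshot, seeds, input digests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in inputs.items()
            if p and Path(p).exists()
        },
        "moable_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
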