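"""Reproducibility manifests: every CLI subcommand records its command line,
effective configuration, seeds, input checksums and version."""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time

from . import __version__

__all__ = ["write_manifest", "file_sha256"]


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str,
    command: str,
    config: dict,
    seed: int | None = None,
    inputs: list[str] | None = None,
) -> str:
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "inputs": {p: file_sha256(p) for p in (inputs or []) if os.path.exists(p)},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = os.path.join(outdir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
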