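"""Run manifests: reproducibility plumbing for the analysis scripts.

Every analysis driver records what it ran (command, configuration hash,
seeds, package versions, inputs/outputs, timestamp) as a JSON manifest next
to its outputs, so each artifact on disk is traceable to one manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List

__all__ = ["RunManifest", "config_hash"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["config_hash"] = config_hash(self.config)
        payload["python"] = sys.version.split()[0]
        payload["platform"] = platform.platform()
        payload["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        try:
            from importlib.metadata import version

            payload["kv4pace_version"] = version("kv4pace")
        except Exception:
            payload["kv4pace_version"] = "unknown"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1, default=str))
        return path
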