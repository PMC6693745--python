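"""Result serialization: deterministic CSV/JSON writers with a manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .solver import Solution


def solution_frame(sol: Solution) -> pd.DataFrame:
    """A steady state as a tidy two-section table (node pressures [mmHg],
    then fluxes [ml/min]), rows in canonical order for one-to-one audit
    against the published reference layout."""
    rows = [{"section": "pressure", "name": k, "value": v}
            for k, v in sol.state.to_dict().items()]
    rows.append({"section": "pressure", "name": "P_LC", "value": sol.P_LC})
    rows += [{"section": "flow", "name": k, "value": v}
             for k, v in sol.flows.to_dict().items()]
    rows += [{"section": "transmural", "name": k, "value": v}
             for k, v in sol.transmural.to_dict().items()]
    rows += [{"section": "resistance", "name": k, "value": v}
             for k, v in sol.resistances.items()]
    return pd.DataFrame(rows, columns=["section", "name", "value"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(results: dict, out_dir: str | Path) -> dict:
    """Write result artefacts to ``out_dir`` and return a file manifest.

    Recognized keys in ``results``:

    ``baseline``  a :class:`Solution`       -> baseline_solution.csv
    ``sweep``     a tidy DataFrame          -> sweep.csv
    ``collapse``  a CollapseReport          -> collapse.json
    ``audit``     an AuditReport            -> audit.json

    Column order and float formatting are deterministic; CSV values
    round-trip losslessly (17 significant digits).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "baseline" in results:
        path = out / "baseline_solution.csv"
        solution_frame(results["baseline"]).to_csv(
            path, index=False, float_format="%.17g")
        written.append(path)
    if "sweep" in results:
        path = out / "sweep.csv"
        results["sweep"].to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    if "collapse" in results:
        path = out / "collapse.json"
        path.write_text(json.dumps(results["collapse"].to_json_dict(),
                                   indent=2, sort_keys=True) + "\n")
        written.append(path)
    if "audit" in results:
        path = out / "audit.json"
        path.write_text(results["audit"].to_json() + "\n")
        written.append(path)

    manifest = {p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
                for p in written}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    return manifest
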