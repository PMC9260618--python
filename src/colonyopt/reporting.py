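"""Report serialization: TSV tables with a provenance header.

Every output file starts with ``# key=value`` comment lines (tool version,
config hash, seed, subcommand, solver tolerances) so a result can be traced to
the exact inputs that produced it.  Headers contain no timestamps: the same
inputs yield byte-identical files.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from . import __version__
from .allocation import ACTIVE_TOL, MRS_TOL

__all__ = ["RunRecord", "write_report", "read_report", "config_hash"]

FLOAT_FORMAT = "%.12g"


def config_hash(scenario) -> str:
    """Stable hash of a scenario's canonical YAML form."""
    import yaml

    text = yaml.safe_dump(scenario.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance carried in every output file header."""

    subcommand: str
    seed: Optional[int] = None
    config_hash: Optional[str] = None
    tolerances: Dict[str, float] = field(
        default_factory=lambda: {"active_tol": ACTIVE_TOL, "mrs_tol": MRS_TOL}
    )
    tool_version: str = __version__

    def header_lines(self) -> list:
        lines = [
            f"# colonyopt version={self.tool_version}",
            f"# subcommand={self.subcommand}",
        ]
        if self.seed is not None:
            lines.append(f"# seed={self.seed}")
        if self.config_hash is not None:
            lines.append(f"# config_hash={self.config_hash}")
        for k in sorted(self.tolerances):
            lines.append(f"# {k}={self.tolerances[k]:g}")
        return lines


def write_report(
    report,
    path: Union[str, Path],
    fmt: str = "tsv",
    run_record: Optional[RunRecord] = None,
) -> None:
    """Write a report (anything with ``to_frame()``, or a DataFrame) as TSV.

    Floats are printed at 12 significant digits with a stable column order;
    an empty table still writes its header line.  The optional RunRecord goes
    first as ``#`` comment lines.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported report format {fmt!r}")
    df = report if isinstance(report, pd.DataFrame) else report.to_frame()
    buf = io.StringIO()
    if run_record is not None:
        for line in run_record.header_lines():
            buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT)
    Path(path).write_text(buf.getvalue())


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV report back, skipping the provenance header."""
    return pd.read_csv(path, sep="\t", comment="#")
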