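"""CSV serialization with schema checking and provenance headers.

All artifacts are small flat tables; files carry unit-suffixed column
names and a comment header recording the fully resolved configuration and
package version, so every output is reproducible from its own metadata.
Numbers are written with 12 significant digits (locale-independent, dot
decimal separator), which round-trips all quantities in this package to
well below model tolerances.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .errors import SchemaError

SCHEMAS: dict[str, list[str]] = {
    "trajectory": ["t_s", "x_m", "v_mps", "p_m", "q_m", "step_idx"],
    "step-table": [
        "n",
        "t_mid_s",
        "q_m",
        "v_mps",
        "p_m",
        "p_next_m",
        "delta_p_m",
        "parity",
    ],
    "region": ["b_p", "b_d", "rho", "stable"],
    "sweep": ["cadence_spm", "t_step_s", "bp_min", "bp_max", "bd_min", "bd_max"],
    "deviation": ["system", "b_p", "b_d", "n", "t_mid_s", "deviation_norm"],
}

FLOAT_FORMAT = "%.12g"


def _check_schema(columns, schema: str) -> None:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in columns]
    extra = [c for c in columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"columns do not match schema {schema!r}: "
            f"missing {missing or 'none'}, extra {extra or 'none'}"
        )


def write_table(
    df: pd.DataFrame,
    path,
    schema: str,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a schema-checked CSV with '#'-prefixed provenance header lines."""
    _check_schema(list(df.columns), schema)
    df = df[SCHEMAS[schema]]
    with open(path, "w", newline="") as fh:
        from . import __version__

        fh.write(f"# gaitstab {__version__} schema={schema}\n")
        for key, value in (provenance or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, verifying its columns."""
    df = pd.read_csv(path, comment="#")
    _check_schema(list(df.columns), schema)
    return df[SCHEMAS[schema]]
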