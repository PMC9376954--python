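"""Run configuration: every tunable of the toolkit with provenance tags.

Each entry is tagged ``model`` (a fixed constant of the published parameter
set), ``scan`` (one of the two deliberately scanned parameters), or
``assumption`` (a default this package had to choose; its rationale lives
in docs/methods.md).  Configurations round-trip losslessly through a flat
``key = value  ; provenance`` text format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

PROVENANCES = ("model", "scan", "assumption")


@dataclass
class ConfigEntry:
    value: object
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


def default_config() -> dict[str, ConfigEntry]:
    """The full tunable surface with defaults and provenance."""
    e = ConfigEntry
    return {
        # force field scan parameters
        "sigma_SS": e(0.41, "scan"),
        "r0_BS": e(0.55, "scan"),
        # force-field numerical choices
        "nonbonded_cutoff": e(1.2, "assumption"),
        "shift_at_cutoff": e(True, "assumption"),
        "angle_form": e("cosine", "assumption"),
        "repulsive_form": e("r12", "assumption"),
        "sigma_combination": e("arithmetic", "assumption"),
        "bead_mass": e(72.0, "assumption"),
        # dynamics protocol
        "dt_fs": e(15.0, "model"),
        "temperature": e(303.0, "model"),
        "tau_ps": e(0.17, "model"),
        "box": e(35.0, "model"),
        "n_chains": e(72, "model"),
        "n_residues": e(8, "model"),
        "insertion_floor": e(0.5, "assumption"),
        # analysis
        "cluster_cutoff": e(0.55, "model"),
        "cluster_include_terminals": e(True, "assumption"),
        "cbb_shell_lo": e(0.8, "model"),
        "cbb_shell_hi": e(2.4, "model"),
        # phase boundaries (fitted to fixtures, not reference data)
        "phase_cbb_single": e(0.8, "assumption"),
        "phase_cn_multi": e(0.6, "assumption"),
        "phase_cbb_multi": e(0.5, "assumption"),
        "phase_cn_glass": e(0.4, "assumption"),
        "phase_cbb_glass": e(0.4, "assumption"),
        # kinetics
        "kinetics_volume": e(35.0 ** 3, "model"),
        "kinetics_N": e(72, "model"),
        "fit_n_starts": e(5, "assumption"),
        "fit_equal_weights": e(True, "assumption"),
    }


def _render(v: object) -> str:
    return repr(v) if isinstance(v, str) else str(v)


def _parse(s: str) -> object:
    s = s.strip()
    if s.startswith(("'", '"')) and s.endswith(("'", '"')):
        return s[1:-1]
    if s == "True":
        return True
    if s == "False":
        return False
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def save_config(config: dict[str, ConfigEntry], path) -> None:
    lines = ["# twobead run configuration"]
    for key, entry in config.items():
        lines.append(f"{key} = {_render(entry.value)}  ; {entry.provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> dict[str, ConfigEntry]:
    config: dict[str, ConfigEntry] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: malformed config line {raw!r}")
        key, rest = (s.strip() for s in line.split("=", 1))
        if ";" in rest:
            value_s, prov = (s.strip() for s in rest.rsplit(";", 1))
        else:
            value_s, prov = rest, "assumption"
        config[key] = ConfigEntry(_parse(value_s), prov)
    return config


def assumptions(config: dict[str, ConfigEntry] | None = None) -> dict[str, object]:
    """All assumption-tagged defaults (for the --show-assumptions flag)."""
    cfg = config if config is not None else default_config()
    return {k: e.value for k, e in cfg.items() if e.provenance == "assumption"}
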