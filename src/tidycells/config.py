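"""Package-level display/behaviour options, optionally loaded from YAML."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Options:
    #: word used in the first display-header line ("# A <flavor>-table abstraction: ...")
    flavor: str = "Cell"
    #: separator between reduction name and 1-based dim index ("" -> PC1, "_" -> PC_1)
    reduction_separator: str = ""
    #: default per-cell total for log-normalization
    scale_total: float = 10_000.0


#: mutable global defaults; CLI flags and function arguments override these
options = Options()


def load_config(path) -> Options:
    """Read options from a YAML file and install them as the global defaults.

    Unknown keys are ignored; missing keys keep their current value.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("flavor", "reduction_separator", "scale_total"):
        if key in raw:  # mutate in place: other modules hold this object
            setattr(options, key, raw[key])
    return options
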