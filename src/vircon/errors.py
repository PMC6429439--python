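"""Error hierarchy mapped onto CLI exit codes.

0 = ok, 2 = configuration, 3 = data format, 4 = data integrity.
"""


class VirconError(Exception):
    """Base class; carries the process exit code for the CLI layer."""

    exit_code = 1


class ConfigError(VirconError):
    """Bad or missing configuration (paths, sample names, parameters)."""

    exit_code = 2


class FormatError(VirconError):
    """A file does not conform to its declared format."""

    exit_code = 3


class IntegrityError(VirconError):
    """Inputs are well-formed but mutually inconsistent (e.g. a VCF REF
    allele disagreeing with the reference genome)."""

    exit_code = 4


class CoordinateError(IntegrityError):
    """A feature or variant falls outside its chromosome bounds."""
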