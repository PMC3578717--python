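"""Exception hierarchy; the CLI maps these onto exit codes."""


class FluidMSError(Exception):
    """Base class for all package errors."""


class InputError(FluidMSError):
    """Malformed or missing input data (FASTA, MGF, tables). Exit code 2."""


class ConfigError(FluidMSError):
    """Invalid configuration: panel files, rule definitions, settings. Exit code 3."""
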