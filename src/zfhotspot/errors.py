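"""Exception hierarchy for the zfhotspot pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, InputError -> 3,
anything else raised inside a stage -> 4.
"""


class ZFHotspotError(Exception):
    """Base class for all package errors."""


class ConfigError(ZFHotspotError):
    """Invalid or inconsistent configuration."""


class InputError(ZFHotspotError):
    """Invalid input data (bad sequence, malformed file, inconsistent counts)."""


class SchemaError(InputError):
    """A tabular input is missing required columns."""


class ReferenceMismatchError(InputError):
    """Reported reference allele disagrees with the gene-model sequence."""

    def __init__(self, expected: str, observed: str, where: str = ""):
        self.expected = expected
        self.observed = observed
        msg = f"reference mismatch{f' at {where}' if where else ''}: " \
              f"model has {expected!r}, record has {observed!r}"
        super().__init__(msg)
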