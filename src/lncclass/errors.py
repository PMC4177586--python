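"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage 2, input/format 3,
model mismatch 4).
"""


class LncclassError(Exception):
    """Base class for package errors."""


class InputError(LncclassError):
    """Malformed, empty or otherwise unusable user input."""


class ModelMismatchError(LncclassError):
    """A model archive does not match the feature space it is applied to."""
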