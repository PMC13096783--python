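"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: input/format problems exit 2,
configuration problems exit 3. Contract errors indicate misuse of the
library API and surface as ordinary tracebacks.
"""


class EdaLayoutError(Exception):
    """Base class for all package errors."""


class InputFormatError(EdaLayoutError):
    """Malformed input data (bad CSV, duplicate headers, unreadable file)."""

    exit_code = 2


class CoercionError(InputFormatError):
    """A column could not be coerced to its declared role."""


class ConfigError(EdaLayoutError):
    """Invalid or inconsistent configuration / options."""

    exit_code = 3


class ContractError(EdaLayoutError, ValueError):
    """An API precondition was violated by the caller."""
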