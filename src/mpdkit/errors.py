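"""Exception hierarchy shared across the toolkit.

Every user-facing validation failure raises :class:`ValidationError` (or a
subclass) so the command-line layer can map it to a single-line error and
exit code 1, distinct from programming errors.
"""


class ValidationError(ValueError):
    """Invalid user input: malformed table, unknown vocabulary value, etc."""


class NamespaceError(ValidationError):
    """Unregistered or duplicate identifier namespace."""


class FormatError(ValidationError):
    """A file failed to parse; carries file and line context when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        context = ""
        if path is not None:
            context = f"{path}:{line}: " if line is not None else f"{path}: "
        super().__init__(context + message)
        self.path = path
        self.line = line
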