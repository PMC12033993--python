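class ValidationError(ValueError):
    """Raised when an input violates a documented precondition.

    The CLI maps this to exit code 2; all other failures exit 1.
    """
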