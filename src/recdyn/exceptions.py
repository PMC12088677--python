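class FitError(RuntimeError):
    """A model fit failed or the data cannot constrain the model."""
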