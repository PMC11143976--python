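"""Physical constants."""

#: Standard gravitational acceleration, m/s^2.
GRAVITY: float = 9.81

#: Ordered study conditions: baseline, then recovery time points after the
#: fatigue protocol.
CONDITIONS: tuple[str, ...] = ("baseline", "3min", "10min", "1hr", "24hr")
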