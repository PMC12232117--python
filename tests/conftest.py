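from hypothesis import HealthCheck, settings

# reproducible property tests: same examples on every run
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")
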