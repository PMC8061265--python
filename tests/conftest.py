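import logging

from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the default-efficiency warning fires on every quantify call without curves
logging.getLogger("cceamp.qpcr").setLevel(logging.ERROR)
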