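"""Frame quantization of exposure durations for display devices.

A display can only show a stimulus for whole multiples of its frame time
(10 ms at 100 Hz; 13.3 ms at 75 Hz), so nominal exposure targets must be
snapped to the nearest achievable multiple.  Ties are broken toward the
longer duration, which is what maps a 20 ms target at 75 Hz to 2 frames
(26.7 ms, displayed as 27) rather than 1.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DeviceProfile",
    "CRT_PROFILE",
    "HMD_PROFILE",
    "CRT_TARGET_DURATIONS_MS",
    "quantize_duration",
    "device_design",
]

#: Nominal exposure targets of the CRT design, ms (multiples of the 10 ms frame).
CRT_TARGET_DURATIONS_MS = (10.0, 20.0, 50.0, 80.0, 140.0, 200.0)


@dataclass(frozen=True)
class DeviceProfile:
    """A display device characterized by its refresh rate."""

    name: str
    refresh_hz: float

    def __post_init__(self):
        if not self.refresh_hz > 0:
            raise ValueError("refresh_hz must be > 0")

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.refresh_hz


CRT_PROFILE = DeviceProfile("CRT", 100.0)
HMD_PROFILE = DeviceProfile("HMD", 75.0)


def quantize_duration(target_ms: float, frame_ms: float) -> tuple[int, float, int]:
    """Snap a target duration to a whole number of display frames.

    Returns ``(n_frames, nominal_ms, display_ms)`` where ``n_frames`` is the
    positive frame count minimizing ``|target - k * frame_ms|`` (ties toward
    the larger ``k``), ``nominal_ms`` the exact achieved duration and
    ``display_ms`` that duration rounded to integer milliseconds.
    """
    if not (target_ms > 0 and frame_ms > 0):
        raise ValueError("target_ms and frame_ms must be positive")
    k_lo = max(1, int(target_ms // frame_ms))
    k_hi = k_lo + 1
    # tie goes to the larger count; tolerance absorbs float round-off in
    # non-terminating frame times (e.g. 1000/75 ms)
    tie_tol = 1e-9 * max(1.0, target_ms)
    k = k_hi if abs(k_hi * frame_ms - target_ms) <= abs(k_lo * frame_ms - target_ms) + tie_tol else k_lo
    nominal = k * frame_ms
    return k, nominal, int(round(nominal))


def device_design(profile: DeviceProfile, target_durations_ms=CRT_TARGET_DURATIONS_MS):
    """Build the whole-report session design for a device.

    Quantizes the six target durations to the device's frame time and
    returns a :class:`tvawr.simulate.DesignSpec`.  On the 100 Hz CRT the
    targets are exact frame multiples and come through unchanged; at 75 Hz
    they become the displayed set {13, 27, 53, 80, 147, 200} ms.
    """
    from .simulate import DesignSpec  # local import to avoid a cycle

    if len(target_durations_ms) != 6:
        raise ValueError("a session design needs exactly 6 target durations")
    quantized = [quantize_duration(t, profile.frame_ms) for t in target_durations_ms]
    nominals = [q[1] for q in quantized]
    if len(set(q[2] for q in quantized)) != 6:
        raise ValueError(
            f"target durations collapse after quantization on {profile.name}: "
            f"{[q[2] for q in quantized]}"
        )
    return DesignSpec(
        device=profile.name,
        exposure_durations_ms=tuple(sorted(nominals)),
        target_durations_ms=tuple(sorted(target_durations_ms)),
    )
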