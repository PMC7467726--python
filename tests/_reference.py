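"""Straight-line reference implementations used as independent oracles.

These deliberately avoid the package's grid/field machinery: plain
arithmetic transcribed directly from the model rules, kept separate from
the code paths they check.
"""


def reference_block_update(state, C, N, local, p, rng):
    """One switch-plus-metabolism pass for a single block.

    Returns (state', C', N', secreted, consumed, switched). ``p`` is any
    object with the model parameter attributes; ``rng`` supplies uniform
    draws (consumed only when the switching threshold condition holds).
    """
    if state == "dark":
        if local > p.T_DL and rng.random() < p.P_DL:
            return "light", C, N, 0.0, 0.0, True
        N = N + p.f * p.AspU * p.Cmax
        c_tmp = C + (1.0 - p.f) * p.AspU * p.Cmax * p.Y
        secreted = min(p.Pf * c_tmp, p.secretion_cap)
        return "dark", c_tmp - secreted, N, secreted, 0.0, False
    if local < p.T_LD and rng.random() < p.P_LD:
        return "dark", C, N, 0.0, 0.0, True
    consumed = min(local, p.Cmax)
    return "light", C + consumed, N + p.AspU * p.Cmax, 0.0, consumed, False


def reference_disk_count(radius):
    """Count integer lattice points (x, y) with x**2 + y**2 <= radius**2
    by brute-force enumeration."""
    r = int(radius) + 1
    return sum(1 for x in range(-r, r + 1) for y in range(-r, r + 1)
               if x * x + y * y <= radius * radius)
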