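"""Independent reference implementations used only to cross-check the
package. Nothing here imports from poreflux's computational paths."""

import numpy as np


def butter_lowpass_coeffs(order: int, cutoff: float, dt: float):
    """Digital Butterworth low-pass (b, a) built from first principles.

    Analog prototype poles on the unit circle, frequency prewarping, and a
    bilinear transform — no scipy.signal involvement.
    """
    T = dt
    warped = 2.0 / T * np.tan(np.pi * cutoff * T)  # prewarped analog cutoff
    k = np.arange(1, order + 1)
    proto = np.exp(1j * np.pi * (2 * k + order - 1) / (2 * order))  # |s|=1 poles
    s_poles = warped * proto
    z_poles = (1 + s_poles * T / 2) / (1 - s_poles * T / 2)
    z_zeros = -np.ones(order)
    b = np.real(np.poly(z_zeros))
    a = np.real(np.poly(z_poles))
    # unity DC gain
    b *= np.sum(a) / np.sum(b)
    return b, a


def direct_form_filter(b, a, x):
    """Plain difference-equation recursion (direct form I), zero ICs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.zeros_like(x)
    nb, na = len(b), len(a)
    for n in range(len(x)):
        acc = 0.0
        for i in range(nb):
            if n - i >= 0:
                acc += b[i] * x[n - i]
        for j in range(1, na):
            if n - j >= 0:
                acc -= a[j] * y[n - j]
        y[n] = acc / a[0]
    return y


def zero_phase_oracle(x, dt, cutoff=10.0, order=3, pad=400):
    """Forward-backward Butterworth with odd-reflection padding.

    Edge transients from the zero initial conditions die out inside the
    pad, so interior samples are a faithful zero-phase reference.
    """
    x = np.asarray(x, dtype=np.float64)
    b, a = butter_lowpass_coeffs(order, cutoff, dt)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2 : -pad - 2 : -1]
    ext = np.concatenate([left, x, right])
    y = direct_form_filter(b, a, ext)
    y = direct_form_filter(b, a, y[::-1])[::-1]
    return y[pad : pad + len(x)]


def points_in_cylinders(points, centers, radii, height):
    """Brute-force point-in-cylinder assignment: (N, C) boolean matrix."""
    points = np.asarray(points, dtype=np.float64)
    out = np.zeros((len(points), len(radii)), dtype=bool)
    for i, p in enumerate(points):
        for c in range(len(radii)):
            z_lo = centers[c, 2] - height / 2
            z_hi = centers[c, 2] + height / 2
            dxy = np.hypot(p[0] - centers[c, 0], p[1] - centers[c, 1])
            out[i, c] = (z_lo <= p[2] < z_hi) and (dxy <= radii[c])
    return out


def pairwise_count_within(center, others, cutoff):
    """Brute-force count of points within an inclusive cutoff of center."""
    n = 0
    for q in np.asarray(others, dtype=np.float64):
        if np.sqrt(np.sum((q - np.asarray(center)) ** 2)) <= cutoff:
            n += 1
    return n


def run_length_dwells(labels, dt):
    """RLE oracle: list of (label, n_frames * dt) for maximal runs."""
    out = []
    i = 0
    labels = list(labels)
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], (j - i) * dt))
        i = j
    return out
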