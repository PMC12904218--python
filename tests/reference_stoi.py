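"""Independent reference STOI, written as plain loops from the published
algorithm description.  Deliberately unvectorised and structured differently
from the package implementation so it can serve as an oracle."""

import numpy as np
from scipy.signal import resample_poly


def _thirdoct_bounds(fs, nfft, n_bands, min_freq):
    f = np.linspace(0, fs, nfft + 1)[:nfft // 2 + 1]
    bounds = []
    for k in range(n_bands):
        lo = min_freq * 2.0 ** ((2 * k - 1) / 6.0)
        hi = min_freq * 2.0 ** ((2 * k + 1) / 6.0)
        i_lo = int(np.argmin((f - lo) ** 2))
        i_hi = int(np.argmin((f - hi) ** 2))
        bounds.append((i_lo, i_hi))
    return bounds


def reference_stoi(clean, degraded, sample_rate):
    fs, framelen, hop, nfft = 10_000, 256, 128, 512
    n_bands, min_freq, seg_n = 15, 150.0, 30
    beta_clip = 10.0 ** (15.0 / 20.0)   # -15 dB SDR bound
    dyn_range = 40.0
    eps = np.finfo(np.float64).eps

    if sample_rate != fs:
        g = np.gcd(int(sample_rate), fs)
        clean = resample_poly(clean, fs // g, sample_rate // g)
        degraded = resample_poly(degraded, fs // g, sample_rate // g)
    w = np.hanning(framelen + 2)[1:-1]

    # frame, drop silent frames (clean energy > 40 dB below loudest)
    frames_c, frames_d = [], []
    for start in range(0, len(clean) - framelen + 1, hop):
        frames_c.append(clean[start:start + framelen] * w)
        frames_d.append(degraded[start:start + framelen] * w)
    energies = [20 * np.log10(np.linalg.norm(fr) + eps) for fr in frames_c]
    emax = max(energies)
    keep_c = [fr for fr, e in zip(frames_c, energies) if e > emax - dyn_range]
    keep_d = [fr for fr, e in zip(frames_d, energies) if e > emax - dyn_range]

    # overlap-add back, then re-frame for the DFT (mirrors the method's
    # silent-frame removal on the waveform)
    def ola(frames):
        out = np.zeros(framelen + hop * (len(frames) - 1))
        for m, fr in enumerate(frames):
            out[m * hop:m * hop + framelen] += fr
        return out

    x, y = ola(keep_c), ola(keep_d)
    specs_c, specs_d = [], []
    for start in range(0, len(x) - framelen + 1, hop):
        specs_c.append(np.fft.rfft(x[start:start + framelen] * w, nfft))
        specs_d.append(np.fft.rfft(y[start:start + framelen] * w, nfft))

    bounds = _thirdoct_bounds(fs, nfft, n_bands, min_freq)
    env_c = np.zeros((n_bands, len(specs_c)))
    env_d = np.zeros((n_bands, len(specs_d)))
    for m in range(len(specs_c)):
        for j, (lo, hi) in enumerate(bounds):
            env_c[j, m] = np.sqrt(np.sum(np.abs(specs_c[m][lo:hi]) ** 2))
            env_d[j, m] = np.sqrt(np.sum(np.abs(specs_d[m][lo:hi]) ** 2))

    total, count = 0.0, 0
    for m in range(seg_n, env_c.shape[1] + 1):
        for j in range(n_bands):
            xx = env_c[j, m - seg_n:m]
            yy = env_d[j, m - seg_n:m].copy()
            scale = np.linalg.norm(xx) / (np.linalg.norm(yy) + eps)
            yy = yy * scale
            for i in range(seg_n):
                bound = xx[i] * (1 + beta_clip)
                if yy[i] > bound:
                    yy[i] = bound
            xc = xx - xx.mean()
            yc = yy - yy.mean()
            denom = np.linalg.norm(xc) * np.linalg.norm(yc) + eps
            total += float(np.dot(xc, yc) / denom)
            count += 1
    return total / count
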