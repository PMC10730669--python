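"""Maturation-delay kernels: means, truncation constants and percentile shifts.

Builds Erlang kernels of several shapes at the same mean delay, places the
truncation shift at the 99th percentile, and prints the derived constants.
"""

from delaylv import KernelSpec, alpha, percentile_shift, truncated_mean

print("Erlang maturation kernels with mean delay p/beta = 2 time units")
print(f"{'p':>4} {'beta':>8} {'Delta(99%)':>12} {'alpha':>8} {'trunc. mean':>12}")
for p in (1, 2, 10, 20):
    beta = p / 2.0
    delta = percentile_shift(p, beta, 0.99)
    spec = KernelSpec(p, beta, delta)
    print(f"{p:>4} {beta:>8.3f} {delta:>12.4f} {alpha(spec):>8.4f} {truncated_mean(spec):>12.4f}")

print()
print("Higher shape = more deterministic maturation: the 99th-percentile shift")
print("shrinks toward the mean and the truncated mean approaches p/beta.")
print()
print("Published truncation shifts recovered by percentile inversion:")
for label, p, beta in [
    ("shape 1,  rate 1    ", 1, 1.0),
    ("shape 20, rate 20   ", 20, 20.0),
    ("shape 1,  rate 1/8  ", 1, 1 / 8),
    ("shape 20, rate 20/8 ", 20, 2.5),
]:
    print(f"  {label} -> Delta = {percentile_shift(p, beta, 0.99):.2f}")
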