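# South Africa province contiguity (queen/land-border), one edge per line.
# Labels: EC Eastern Cape, FS Free State, Gau Gauteng, KN KwaZulu-Natal,
# Lim Limpopo, Mp Mpumalanga, NC Northern Cape, NW North West, WC Western Cape.
# Hand-coded from public province boundaries (every pair of provinces that
# shares a land border); shipped as test/demo data, 17 edges, connected.
EC WC
EC NC
EC FS
EC KN
FS NC
FS NW
FS Gau
FS Mp
FS KN
Gau NW
Gau Lim
Gau Mp
KN Mp
Lim Mp
Lim NW
NC WC
NC NW
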