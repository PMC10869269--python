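# structural-state substitution matrix, half-bit units
# background 0.0693935 0.00169252 0.0406206 0.05811 0.0739069 0.0262341 0.0174894 0.035543 0.0369535 0.0330042 0.0267983 0.00394922 0.109732 0.0961918 0.136812 0.0564175 0.0220028 0.042031 0.0744711 0.038646
  A B C D E F G H I J K L M N O P Q R S T
A   7  -1  -5  -4  -6  -9   0  -3  -8 -10  -9  -4  -6  -3  -9   0  -9  -5  -2  -4
B  -1   9   0  -1  -2   1   3   0   0   1   1   9  -3  -2  -3  -1   2   0   1   2
C  -5   0   7   1  -1  -1  -7  -3  -1   1  -5  -2  -7 -10  -1 -10   2   1  -8  -4
D  -4  -1   1   6  -2   1  -8   2  -2  -1  -4  -3  -8  -4   0  -6   1   1  -5   1
E  -6  -2  -1  -2   7  -4  -2  -6  -5  -4  -5   1  -7  -7  -5  -8  -3  -3  -1  -2
F  -9   1  -1   1  -4   7  -5  -3   0   3   1  -1  -9 -10   2  -9   0   0  -6  -1
G   0   3  -7  -8  -2  -5  10  -2  -6  -3  -5   0  -5  -9 -10  -4  -5   0   1  -3
H  -3   0  -3   2  -6  -3  -2   7  -3  -1  -2  -2  -3  -2  -2  -1  -3   1  -4   1
I  -8   0  -1  -2  -5   0  -6  -3   7   1  -2  -2  -5  -7   2  -6   5  -5  -9  -7
J -10   1   1  -1  -4   3  -3  -1   1   7  -2  -2  -7 -11   1  -9   2   0 -10  -3
K  -9   1  -5  -4  -5   1  -5  -2  -2  -2   9   4  -6 -10   1  -9  -3  -8 -10  -8
L  -4   9  -2  -3   1  -1   0  -2  -2  -2   4  13  -5  -5  -6  -3  -1  -2  -1   0
M  -6  -3  -7  -8  -7  -9  -5  -3  -5  -7  -6  -5   5   3 -10  -2 -10   0   0  -5
N  -3  -2 -10  -4  -7 -10  -9  -2  -7 -11 -10  -5   3   4  -9  -5  -8  -7   1   0
O  -9  -3  -1   0  -5   2 -10  -2   2   1   1  -6 -10  -9   4 -10   0  -4 -10  -4
P   0  -1 -10  -6  -8  -9  -4  -1  -6  -9  -9  -3  -2  -5 -10   7  -8  -8  -2  -4
Q  -9   2   2   1  -3   0  -5  -3   5   2  -3  -1 -10  -8   0  -8   8  -7  -9  -4
R  -5   0   1   1  -3   0   0   1  -5   0  -8  -2   0  -7  -4  -8  -7   7  -5  -2
S  -2   1  -8  -5  -1  -6   1  -4  -9 -10 -10  -1   0   1 -10  -2  -9  -5   6  -1
T  -4   2  -4   1  -2  -1  -3   1  -7  -3  -8   0  -5   0  -4  -4  -4  -2  -1   7
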