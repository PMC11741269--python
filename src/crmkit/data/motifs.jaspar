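>FOX	FOX
A  [  1  1  1  1  1 97  1 ]
C  [  1  1  1  1  1  1 97 ]
G  [  1 97  1  1  1  1  1 ]
T  [ 97  1 97 97 97  1  1 ]
>SOX	SOX
A  [ 97 97  1 97 97  1  1 ]
C  [  1  1 97  1  1  1  1 ]
G  [  1  1  1  1  1  1 97 ]
T  [  1  1  1  1  1 97  1 ]
>POU	POU
A  [ 97  1  1  1 97 97 97  1 ]
C  [  1  1  1 97  1  1  1  1 ]
G  [  1  1 97  1  1  1  1  1 ]
T  [  1 97  1  1  1  1  1 97 ]
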