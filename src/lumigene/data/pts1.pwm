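# synthetic PTS1 C-terminal tripeptide PWM (canonical classes [SAC][KRH][LM])
# threshold 3.0
A C D E F G H I K L M N P Q R S T V W Y
1.6 1.4 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 2.0 -1.0 -1.0 -1.0 -1.0
-1.0 -1.0 -1.0 -1.0 -1.0 -1.0 1.4 -1.0 2.0 -1.0 -1.0 -1.0 -1.0 -1.0 1.8 -1.0 -1.0 -1.0 -1.0 -1.0
-1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 2.0 1.6 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0
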