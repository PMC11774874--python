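trait_a,trait_b,r,significant
colM,RD,0.76,1
colM,RTD,-0.68,1
colM,SRA,0.52,1
colM,SRL,0.17,0
colM,RDMC,-0.53,1
colM,RNC,-0.56,1
colM,RC:N,0.18,0
colM,RCC,-0.61,1
RD,RTD,-0.68,1
RD,SRA,0.42,1
RD,SRL,-0.02,0
RD,RDMC,-0.56,1
RD,RNC,-0.52,1
RD,RC:N,0.12,0
RD,RCC,-0.65,1
RTD,SRA,-0.90,1
RTD,SRL,-0.57,1
RTD,RDMC,0.92,1
RTD,RNC,0.27,0
RTD,RC:N,0.13,0
RTD,RCC,0.37,1
SRA,SRL,0.81,1
SRA,RDMC,-0.88,1
SRA,RNC,-0.09,0
SRA,RC:N,-0.28,0
SRA,RCC,-0.22,0
SRL,RDMC,-0.63,1
SRL,RNC,-0.04,0
SRL,RC:N,-0.14,0
SRL,RCC,-0.08,0
RDMC,RNC,0.11,0
RDMC,RC:N,0.21,0
RDMC,RCC,0.24,0
RNC,RC:N,-0.81,1
RNC,RCC,0.65,1
RC:N,RCC,-0.23,0
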