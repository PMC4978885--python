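(PHO:1,(AGR:1,((ANN:1,PRA:1):1,(CUS:1,(DIV:1,(HET:1,ANG:1):1):1):1):1):1):0;
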