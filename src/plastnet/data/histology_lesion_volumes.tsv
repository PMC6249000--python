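subject	side	mode	measured	reference
E	left	remaining	184498	268144
E	right	remaining	146047	268665
E	total	remaining	330545	536809
M	left	remaining	129741	268144
M	right	remaining	84877	268665
M	total	remaining	214618	536809
N	left	remaining	159535	268144
N	right	remaining	158787	268665
N	total	remaining	318322	536809
S	left	remaining	94769	268144
S	right	remaining	89512	268665
S	total	remaining	184281	536809
T	left	remaining	178354	268144
T	right	remaining	130254	268665
T	total	remaining	308608	536809
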